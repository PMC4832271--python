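"""Readers and writers for Oxford GEN/SAMPLE files and plain TSV tables.

GEN dialect: one line per SNP with five leading columns
(chromosome, snp_id, position, alleleA, alleleB) followed by three genotype
probabilities per subject, P(AA), P(AB), P(BB).  Allele B is the dosage
(minor) allele, so dosage = P(AB) + 2 P(BB).  The companion SAMPLE file
carries the binary phenotype in its first phenotype column (Oxford type
"B": 0 = control, 1 = case).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .simulate import CaseControlDataset

logger = logging.getLogger(__name__)

__all__ = [
    "write_gen_sample",
    "read_gen_sample",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_annotation_tsv",
]

PROB_SUM_TOL = 1e-3


def write_gen_sample(dataset: CaseControlDataset, gen_path, sample_path, chrom: str = "2") -> None:
    """Write a dataset as a GEN/SAMPLE pair.

    Dosages are converted to genotype probabilities by splitting mass
    between the two nearest hard genotypes, which round-trips the dosage
    exactly: d <= 1 gives (1-d, d, 0), d > 1 gives (0, 2-d, d-1).
    """
    D = dataset.dosages
    N, M = D.shape
    with open(gen_path, "w") as gen:
        for m in range(M):
            d = D[:, m]
            p_ab = np.where(d <= 1.0, d, 2.0 - d)
            p_bb = np.where(d <= 1.0, 0.0, d - 1.0)
            p_aa = 1.0 - p_ab - p_bb
            probs = np.empty(3 * N)
            probs[0::3], probs[1::3], probs[2::3] = p_aa, p_ab, p_bb
            fields = [chrom, dataset.snp_ids[m], str(int(dataset.positions[m])), "A", "B"]
            gen.write(" ".join(fields + [format(p, ".6g") for p in probs]) + "\n")
    with open(sample_path, "w") as sample:
        sample.write("ID_1 ID_2 missing pheno\n0 0 0 B\n")
        for i, y in enumerate(dataset.phenotype, start=1):
            sample.write(f"ind_{i} ind_{i} 0 {int(y)}\n")


def read_gen_sample(gen_path, sample_path) -> CaseControlDataset:
    """Read a GEN/SAMPLE pair into a :class:`CaseControlDataset`.

    Probability triples whose sum deviates from 1 by more than 1e-3 trigger
    a warning and are renormalised; malformed lines raise with their line
    number.  The causal SNP, if any, is unknown to the reader.
    """
    phenotype = _read_sample_phenotype(sample_path)
    N = phenotype.size
    snp_ids: list[str] = []
    positions: list[int] = []
    dosage_cols: list[np.ndarray] = []
    with open(gen_path) as gen:
        for lineno, line in enumerate(gen, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 5 + 3 * N:
                raise ValueError(
                    f"{gen_path} line {lineno}: expected {5 + 3 * N} fields for "
                    f"{N} subjects, found {len(fields)}"
                )
            try:
                probs = np.array(fields[5:], dtype=float).reshape(N, 3)
            except ValueError as exc:
                raise ValueError(f"{gen_path} line {lineno}: non-numeric probability ({exc})")
            sums = probs.sum(axis=1)
            off = np.abs(sums - 1.0) > PROB_SUM_TOL
            if off.any():
                warnings.warn(
                    f"{gen_path} line {lineno}: {int(off.sum())} probability triples "
                    "do not sum to 1; renormalising",
                    stacklevel=2,
                )
            probs = probs / sums[:, None]
            snp_ids.append(fields[1])
            positions.append(int(fields[2]))
            dosage_cols.append(probs[:, 1] + 2.0 * probs[:, 2])
    if not dosage_cols:
        raise ValueError(f"{gen_path}: no SNP lines found")
    return CaseControlDataset(
        dosages=np.column_stack(dosage_cols),
        phenotype=phenotype,
        snp_ids=snp_ids,
        positions=np.asarray(positions, dtype=np.int64),
    )


def _read_sample_phenotype(sample_path) -> np.ndarray:
    with open(sample_path) as fh:
        header = fh.readline().split()
        types = fh.readline().split()
        if len(header) < 4 or len(types) != len(header):
            raise ValueError(f"{sample_path}: malformed SAMPLE header")
        col = 3  # first phenotype column after ID_1 ID_2 missing
        if types[col] != "B":
            raise ValueError(f"{sample_path}: phenotype column is not binary (type {types[col]!r})")
        values = []
        for lineno, line in enumerate(fh, start=3):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != len(header):
                raise ValueError(f"{sample_path} line {lineno}: wrong field count")
            values.append(int(fields[col]))
    return np.asarray(values, dtype=np.int8)


def write_dosage_tsv(dataset: CaseControlDataset, path) -> None:
    """Write dosages as TSV: one row per subject, phenotype first column."""
    frame = pd.DataFrame(dataset.dosages, columns=dataset.snp_ids)
    frame.insert(0, "phenotype", dataset.phenotype)
    frame.to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path, positions=None) -> CaseControlDataset:
    frame = pd.read_csv(path, sep="\t")
    if "phenotype" not in frame.columns:
        raise ValueError(f"{path}: missing 'phenotype' column")
    phenotype = frame.pop("phenotype").to_numpy(dtype=np.int8)
    if positions is None:
        positions = np.arange(1, frame.shape[1] + 1, dtype=np.int64)
    return CaseControlDataset(
        dosages=frame.to_numpy(dtype=float),
        phenotype=phenotype,
        snp_ids=list(frame.columns),
        positions=np.asarray(positions, dtype=np.int64),
    )


def write_annotation_tsv(groups, snp_ids, path) -> None:
    pd.DataFrame({"snp_id": list(snp_ids), "group": np.asarray(groups)}).to_csv(
        path, sep="\t", index=False
    )
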