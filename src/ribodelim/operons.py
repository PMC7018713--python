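"""rDNA operon copy-number estimation and flow-cytometric genome sizing.

The ribosomal operon is tandemly repeated, so its read coverage exceeds
that of single-copy genes by a factor equal to the per-genome copy number.
The estimator divides operon coverage by the mean coverage of a curated
single-copy gene panel (genes flagged multi-copy or without a hit are
excluded).  Genome sizes come from the flow-cytometry fluorescence ratio of
dinospores to an internal *Micromonas pusilla* RCC299 standard whose
haploid DNA mass is 20.9 fg, converted at 0.978 Mb per fg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REFERENCE_1C_FG = 20.9
MB_PER_FG = 0.978

VALID_FLAGS = {"ok", "multi_copy", "no_hit"}


@dataclass(frozen=True)
class CopyNumberEstimate:
    strain_id: str
    copies: float          # operon coverage / mean single-copy gene coverage
    copies_median: float   # robust alternative using the median gene coverage
    n_genes_used: int

    @property
    def copies_rounded(self) -> int:
        return round(self.copies)


class CoverageTable:
    """Per-strain coverage of the operon and candidate single-copy genes.

    Backed by a long-format DataFrame with columns ``strain``, ``feature``,
    ``flag`` (ok / multi_copy / no_hit, case-insensitive) and
    ``mean_coverage``; the row whose feature is ``operon`` holds the operon
    coverage (exactly one per strain).
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"strain", "feature", "flag", "mean_coverage"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"coverage table missing columns: {sorted(missing)}")
        frame = frame.copy()
        frame["flag"] = frame["flag"].str.lower()
        bad = set(frame["flag"]) - VALID_FLAGS
        if bad:
            raise ValueError(f"unknown flags: {sorted(bad)}")
        if (frame["mean_coverage"] < 0).any():
            raise ValueError("coverages must be non-negative")
        ops = frame[frame["feature"] == "operon"].groupby("strain").size()
        strains = frame["strain"].unique()
        if not all(ops.get(s, 0) == 1 for s in strains):
            raise ValueError("each strain needs exactly one operon row")
        self.frame = frame

    @property
    def strains(self) -> list[str]:
        return list(self.frame["strain"].unique())

    @classmethod
    def from_tsv(cls, path) -> "CoverageTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"strain": str, "feature": str, "flag": str}))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def genes_of(self, strain: str) -> pd.DataFrame:
        sub = self.frame[(self.frame["strain"] == strain) & (self.frame["feature"] != "operon")]
        if sub.empty:
            raise ValueError(f"unknown strain {strain!r}")
        return sub

    def operon_coverage(self, strain: str) -> float:
        sub = self.frame[(self.frame["strain"] == strain) & (self.frame["feature"] == "operon")]
        if sub.empty:
            raise ValueError(f"unknown strain {strain!r}")
        return float(sub["mean_coverage"].iloc[0])


def select_reference_genes(t: CoverageTable, strain: str) -> list[str]:
    """Genes retained for the single-copy panel: flag ``ok`` only."""
    genes = t.genes_of(strain)
    kept = genes.loc[genes["flag"] == "ok", "feature"].tolist()
    if not kept:
        raise ValueError(f"{strain}: no single-copy reference genes retained")
    return kept


def estimate_operon_copies(t: CoverageTable, strain: str,
                           genes: list[str] | None = None) -> CopyNumberEstimate:
    """Operon copies = operon coverage / mean retained-gene coverage."""
    if genes is None:
        genes = select_reference_genes(t, strain)
    sub = t.genes_of(strain)
    cov = sub.loc[sub["feature"].isin(genes), "mean_coverage"].to_numpy(dtype=float)
    if cov.size == 0:
        raise ValueError(f"{strain}: empty gene panel")
    mean_cov = float(np.mean(cov))
    if mean_cov <= 0:
        raise ValueError(f"{strain}: zero mean single-copy coverage")
    operon = t.operon_coverage(strain)
    if operon <= 0:
        raise ValueError(f"{strain}: operon coverage must be positive")
    return CopyNumberEstimate(
        strain_id=strain,
        copies=operon / mean_cov,
        copies_median=operon / float(np.median(cov)),
        n_genes_used=int(cov.size),
    )


def estimate_all(t: CoverageTable) -> pd.DataFrame:
    rows = []
    for s in t.strains:
        e = estimate_operon_copies(t, s)
        rows.append({"strain": s, "copies": e.copies, "copies_median": e.copies_median,
                     "copies_rounded": e.copies_rounded, "n_genes_used": e.n_genes_used})
    return pd.DataFrame(rows)


def genome_size_from_ratio(ratio: float, reference_fg: float = REFERENCE_1C_FG) -> float:
    """Genome size in Mb from a fluorescence ratio to the 1C standard."""
    if ratio <= 0:
        raise ValueError("fluorescence ratio must be positive")
    return ratio * reference_fg * MB_PER_FG


def copies_size_correlation(copies, sizes) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between copy number and genome size."""
    copies = np.asarray(copies, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if copies.shape != sizes.shape or copies.size < 3:
        raise ValueError("need at least three paired values")
    if np.ptp(copies) == 0 or np.ptp(sizes) == 0:
        raise ValueError("constant vector: correlation undefined")
    r, p = stats.pearsonr(copies, sizes)
    return float(r), float(p)
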