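"""Population-fitness indicators of parasite ribotypes and their host range.

Fitness of a ribotype in a given year is summarized by (i) its maximal
operon-copy-normalized read abundance and (ii) its persistence — the span
in days of the longest run of consecutive samples in which its
(non-normalized) relative read contribution stays above a threshold.
Ribotype-year records grouped by host-range class are compared with a
tie-corrected Kruskal-Wallis omnibus test on log(x+1) data, followed by
Dunn's pairwise post-hoc z tests with Holm adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class FitnessParams:
    #: relative-contribution threshold a sample must exceed to qualify
    persistence_threshold: float = 0.10
    #: denominator of the relative contribution (the parasite community by
    #: default: ribotypes rarely exceed a few percent of total reads, so a
    #: 10% bar is only meaningful within the parasite fraction; both options
    #: are exposed)
    persistence_denominator: str = "parasite_reads"
    #: tolerated date gap (days) between successive samples within one run
    max_gap_days: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.persistence_threshold < 1.0):
            raise ValueError("persistence threshold must lie in (0, 1)")
        if self.persistence_denominator not in ("total_reads", "parasite_reads"):
            raise ValueError("denominator is 'total_reads' or 'parasite_reads'")


@dataclass(frozen=True)
class FitnessRecord:
    ribotype: str
    year: int
    max_normalized_abundance: float
    persistence_days: float
    host_range_class: str


def normalize_abundance(rel_abundance: float, copies: float) -> float:
    """Relative read abundance divided by the ribotype's operon copy number.

    Corrects the multi-copy amplification bias of rDNA metabarcodes: a
    ribotype with many operon copies per genome over-contributes reads per
    cell.
    """
    if copies <= 0:
        raise ValueError("operon copy number must be positive")
    if rel_abundance < 0:
        raise ValueError("relative abundance must be non-negative")
    return rel_abundance / copies


def persistence(dates, contributions, p: FitnessParams | None = None) -> int:
    """Days spanned by the longest qualifying run of consecutive samples.

    A sample qualifies when its relative contribution exceeds the
    threshold.  A run is a maximal stretch of *consecutive samples in the
    series* that all qualify — a present-but-below-threshold sample breaks
    the run — with date gaps between successive samples no larger than
    ``max_gap_days``.  Persistence is ``last - first + 1`` days of the
    longest run, or 0 when no sample qualifies.
    """
    if p is None:
        p = FitnessParams()
    dates = pd.to_datetime(pd.Index(dates))
    if len(dates) != len(contributions):
        raise ValueError("dates and contributions must align")
    if not dates.is_monotonic_increasing:
        raise ValueError("series must be sorted by date")
    best = 0
    run_start = None
    prev_date = None
    for date, c in zip(dates, contributions):
        qualifies = c > p.persistence_threshold
        gap_ok = prev_date is None or (date - prev_date).days <= p.max_gap_days
        if qualifies and run_start is not None and gap_ok:
            best = max(best, (date - run_start).days + 1)
        elif qualifies:
            run_start = date
            best = max(best, 1)
        else:
            run_start = None
        prev_date = date
    return best


def host_range_class(host_matrix: pd.DataFrame, species_of_host: dict[str, str],
                     ribotype_of_strain: dict[str, str],
                     class_map: dict[int, str] | None = None) -> pd.DataFrame:
    """Per-ribotype maximal number of infected host species, classed.

    ``host_matrix``: parasite strains (rows) x host strains (columns),
    binary.  Each host strain must map to a species; the per-strain count
    is the number of *distinct species* infected, and the ribotype value is
    the maximum over its strains.  The default classes follow the grouping
    used for the fitness comparison: {1}, {3}, {4-5}.
    """
    unmapped = [h for h in host_matrix.columns if h not in species_of_host]
    if unmapped:
        raise ValueError(f"host strains without species mapping: {unmapped}")
    if class_map is None:
        class_map = {1: "1", 3: "3", 4: "4-5", 5: "4-5"}
    rows = []
    for strain in host_matrix.index:
        infected = host_matrix.loc[strain]
        species = {species_of_host[h] for h in host_matrix.columns if infected[h] == 1}
        rows.append({"strain": strain, "ribotype": ribotype_of_strain[strain],
                     "n_species": len(species), "empty": len(species) == 0})
    per_strain = pd.DataFrame(rows)
    per_rib = per_strain.groupby("ribotype")["n_species"].max().reset_index()
    per_rib = per_rib.rename(columns={"n_species": "max_host_species"})
    per_rib["host_range_class"] = [
        class_map.get(int(v), str(int(v))) for v in per_rib["max_host_species"]
    ]
    return per_rib


def build_fitness_records(contributions: pd.DataFrame, years: pd.Series,
                          copies_of_ribotype: dict[str, float],
                          class_of_ribotype: dict[str, str],
                          p: FitnessParams | None = None) -> list[FitnessRecord]:
    """One record per ribotype-year from a dated relative-contribution table.

    ``contributions``: samples (DatetimeIndex) x ribotypes, relative read
    contributions on the denominator selected in ``p``; ``years`` labels
    each sample's survey year.
    """
    if p is None:
        p = FitnessParams()
    records = []
    for year in sorted(pd.unique(years)):
        block = contributions.loc[np.asarray(years) == year]
        block = block.sort_index()
        for rib in contributions.columns:
            series = block[rib]
            max_norm = normalize_abundance(float(series.max()), copies_of_ribotype[rib])
            pers = persistence(series.index, series.to_numpy(), p)
            records.append(FitnessRecord(rib, int(year), max_norm, pers,
                                         class_of_ribotype[rib]))
    return records


def dunn_test(groups: dict[str, np.ndarray], adjust: str = "holm") -> pd.DataFrame:
    """Dunn's post-hoc z tests on pooled ranks with tie correction."""
    names = sorted(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    labels = np.concatenate([[g] * len(groups[g]) for g in names])
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    mean_rank = {g: float(ranks[labels == g].mean()) for g in names}
    size = {g: int(np.sum(labels == g)) for g in names}
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            se = np.sqrt(var_base * (1.0 / size[a] + 1.0 / size[b]))
            z = (mean_rank[a] - mean_rank[b]) / se
            rows.append({"group_a": a, "group_b": b, "z": float(z),
                         "p_raw": float(2.0 * stats.norm.sf(abs(z)))})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method=adjust)[1]
    return out


def kruskal_dunn(records: list[FitnessRecord], response: str = "max_abundance",
                 alpha: float = 0.05) -> tuple[float, float, pd.DataFrame | None]:
    """Kruskal-Wallis across host-range classes, Dunn post hoc if significant.

    Responses are log(x+1) transformed.  Returns (H, omnibus p, Dunn table
    or None when the omnibus test does not reject at ``alpha``).
    """
    attr = {"max_abundance": "max_normalized_abundance",
            "persistence": "persistence_days"}[response]
    groups: dict[str, list[float]] = {}
    for r in records:
        groups.setdefault(r.host_range_class, []).append(np.log1p(getattr(r, attr)))
    groups = {g: np.asarray(v) for g, v in groups.items()}
    if len(groups) < 2:
        raise ValueError("need at least two host-range classes")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("each class needs at least two records")
    h, p = stats.kruskal(*groups.values())
    dunn = dunn_test(groups) if p < alpha else None
    return float(h), float(p), dunn
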