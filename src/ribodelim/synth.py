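"""Synthetic study generator with planted ground truth.

Every input the delineation pipeline consumes can be generated here under
known truth: ITS2 sequences on a common four-helix scaffold with an exact
planted matrix of compensatory base changes between ribotypes, per-strain
canonical k-mer profiles with a tunable ribotype core fraction, coverage
tables with planted rDNA operon copy numbers, a multi-year metabarcoding
community driven by Gaussian niche responses to smooth environmental
gradients, and cross-infection host-range plus flow-cytometry phenotype
tables.  Identical seed and configuration give byte-identical outputs.

CBC planting works on the 4-clique of mutually compensatory pair states
{A-U, G-C, U-A, C-G}: each planted pair column assigns every ribotype to
one of at most four states, so the column contributes one CBC to exactly
the ribotype pairs it separates.  The requested matrix is decomposed into
such partition columns (additively "star-shaped" matrices get a direct
construction; anything else goes through an exhaustive small search), and
matrices outside the reachable family raise with the offending ribotype
pair named.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kmer import KmerProfile, canonical
from .structures import StructuredSequence

#: mutually compensatory canonical pair states: any two distinct members
#: differ in both nucleotides while both keep pairing.
_PAIR_CLIQUE = ("AU", "GC", "UA", "CG")

_HELIX_PAIRS = 12
_N_HELICES = 4
_LOOP = 5
_LINKER = 3

#: host species used in the cross-infection design; species 0 is the
#: universally sensitive *Scrippsiella acuminata* STR1 analogue.
HOST_SPECIES = [
    "S_acuminata_STR1", "S_lachrymosa", "S_donghaienis", "Scrippsiella_sp",
    "S_trochoidea", "H_triquetra", "H_rotundata", "H_niei", "H_steinii",
]

DESCRIPTORS = ["temperature", "salinity", "precipitation", "tide_coefficient",
               "NO3", "PO4", "SiOH4"]


class InfeasibleCBCError(ValueError):
    """Requested CBC matrix cannot be realized on the template scaffold."""


def default_cbc_matrix(n_ribotypes: int = 8) -> np.ndarray:
    """Additive default planted matrix, off-diagonal values spanning 1-9.

    Built as ``D[i, j] = c_i + c_j`` with ``c = (0, 1, 1, 2, 2, 3, 4, 5)``
    for eight ribotypes (values 1..9 all occur), or ``c_i = max(i, 1) - (i
    == 0)`` style ramp for other sizes.
    """
    if n_ribotypes == 8:
        c = np.array([0, 1, 1, 2, 2, 3, 4, 5])
    else:
        c = np.arange(n_ribotypes)
    d = c[:, None] + c[None, :]
    np.fill_diagonal(d, 0)
    return d


@dataclass
class SynthConfig:
    n_ribotypes: int = 8
    strains_per_ribotype: int = 8
    planted_cbc: np.ndarray | None = None
    intra_snps: int = 3
    kmer_core_fraction: float = 0.8
    kmer_k: int = 21
    kmer_profile_size: int = 4000
    kmer_core_pool_size: int = 6000
    kmer_background_pool_size: int = 80000
    planted_copies: dict[str, int] | None = None
    copies_range: tuple[int, int] = (58, 270)
    coverage_depth: float = 30.0
    n_samples: int = 48
    n_years: int = 3
    n_taxa: int = 16
    niche_optima: np.ndarray | None = None
    niche_breadth: np.ndarray | float = 0.5
    niche_amplitude: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_ribotypes", "strains_per_ribotype", "n_samples",
                     "n_years", "n_taxa", "intra_snps"):
            if getattr(self, name) < 0 or (name != "intra_snps" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.kmer_core_fraction <= 1.0):
            raise ValueError("kmer_core_fraction must lie in [0, 1]")
        if self.coverage_depth <= 0:
            raise ValueError("coverage_depth must be positive")
        if np.any(np.asarray(self.niche_breadth) <= 0):
            raise ValueError("niche_breadth must be positive")
        if self.planted_cbc is None:
            self.planted_cbc = default_cbc_matrix(self.n_ribotypes)
        m = np.asarray(self.planted_cbc, dtype=np.int64)
        if m.shape != (self.n_ribotypes, self.n_ribotypes):
            raise ValueError("planted_cbc shape must be (n_ribotypes, n_ribotypes)")
        if not np.array_equal(m, m.T):
            raise ValueError("planted_cbc must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("planted_cbc diagonal must be zero")
        if m.min() < 0 or m.max() > 9:
            raise ValueError("planted CBC counts must lie in [0, 9]")
        self.planted_cbc = m

    @property
    def strain_ids(self) -> list[str]:
        return [f"R{r + 1}S{s + 1}"
                for r in range(self.n_ribotypes)
                for s in range(self.strains_per_ribotype)]

    @property
    def ribotype_names(self) -> list[str]:
        return [f"RIB{r + 1}" for r in range(self.n_ribotypes)]


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator, traceable per record."""

    ribotype_of_strain: dict[str, str] = field(default_factory=dict)
    cbc_matrix: np.ndarray | None = None
    copies_of_strain: dict[str, int] = field(default_factory=dict)
    optima: np.ndarray | None = None
    breadth: np.ndarray | None = None
    taxa: list[str] = field(default_factory=list)
    host_class_of_ribotype: dict[str, str] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "ribotype_of_strain": self.ribotype_of_strain,
            "cbc_matrix": None if self.cbc_matrix is None else self.cbc_matrix.tolist(),
            "copies_of_strain": self.copies_of_strain,
            "optima": None if self.optima is None else self.optima.tolist(),
            "breadth": None if self.breadth is None else np.asarray(self.breadth).tolist(),
            "taxa": self.taxa,
            "host_class_of_ribotype": self.host_class_of_ribotype,
            "notes": self.notes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# CBC matrix decomposition into partition columns


def _star_decomposition(d: np.ndarray) -> list[np.ndarray] | None:
    """Exact decomposition when ``d`` is additive (d_ij = c_i + c_j)."""
    r = d.shape[0]
    if r == 2:
        c = np.array([int(d[0, 1]), 0])
    else:
        rows = d.sum(axis=1).astype(float)
        total = rows.sum() / (2 * r - 2)
        c = (rows - total) / (r - 2)
        if not np.allclose(c, np.round(c)) or np.any(c < -1e-9):
            return None
        c = np.round(c).astype(int)
        if not np.array_equal(c[:, None] + c[None, :] - np.diag(2 * c), d):
            return None
    cols = []
    for i in range(r):
        assign = np.zeros(r, dtype=np.int64)
        assign[i] = 1
        cols.extend([assign.copy()] * int(c[i]))
    return cols


def _greedy_decomposition(d: np.ndarray) -> list[np.ndarray]:
    """Partition-cut decomposition by exhaustive small-block search.

    Each step picks the pair with the largest remaining count, fixes its
    two members in distinct blocks, and exhaustively assigns the remaining
    ribotypes to at most four blocks so that every separated pair still
    has a positive remaining count, maximizing the number of pairs served.
    """
    d = d.copy()
    r = d.shape[0]
    cols: list[np.ndarray] = []
    guard = int(d.sum()) + 1
    while d.any():
        guard -= 1
        a, b = np.unravel_index(int(np.argmax(d)), d.shape)
        others = [k for k in range(r) if k not in (a, b)]
        best_assign, best_sep = None, -1
        for combo in itertools.product(range(4), repeat=len(others)):
            assign = np.zeros(r, dtype=np.int64)
            assign[a], assign[b] = 0, 1
            for k, blk in zip(others, combo):
                assign[k] = blk
            sep = 0
            ok = True
            for i in range(r):
                for j in range(i + 1, r):
                    if assign[i] != assign[j]:
                        if d[i, j] < 1:
                            ok = False
                            break
                        sep += 1
                if not ok:
                    break
            if ok and sep > best_sep:
                best_sep, best_assign = sep, assign.copy()
        if best_assign is None or guard < 0:
            raise InfeasibleCBCError(
                f"cannot realize planted CBC count between ribotypes "
                f"{a + 1} and {b + 1}: matrix is not partition-decomposable"
            )
        for i in range(r):
            for j in range(i + 1, r):
                if best_assign[i] != best_assign[j]:
                    d[i, j] -= 1
                    d[j, i] -= 1
        cols.append(best_assign)
    return cols


def decompose_cbc_matrix(d: np.ndarray) -> list[np.ndarray]:
    """Express ``d`` as a sum of partition-cut columns (<=4 blocks each)."""
    if not d.any():
        return []
    star = _star_decomposition(np.asarray(d, dtype=np.int64))
    if star is not None:
        return star
    return _greedy_decomposition(np.asarray(d, dtype=np.int64))


# ---------------------------------------------------------------------------
# ITS2 sequences


def _scaffold_structure() -> str:
    """Four-helix pseudoknot-free scaffold, 48 pair columns."""
    parts = [".."]
    for _ in range(_N_HELICES):
        parts.append("(" * _HELIX_PAIRS + "." * _LOOP + ")" * _HELIX_PAIRS)
        parts.append("." * _LINKER)
    return "".join(parts)[:-_LINKER] + ".."


def gen_ribotype_sequences(config: SynthConfig) -> tuple[list[StructuredSequence], PlantedTruth]:
    """Structured ITS2 sequences for every strain, with exact planted CBCs.

    One template per ribotype descends from a common ancestor on the
    four-helix scaffold; between ribotypes i and j exactly
    ``planted_cbc[i, j]`` pair columns carry double pairing-preserving
    substitutions, and each strain adds at most ``intra_snps`` substitutions
    restricted to unpaired positions (so within-ribotype CBC counts are
    zero by construction).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    structure = _scaffold_structure()
    from .structures import parse_dotbracket

    pt = parse_dotbracket(structure)
    open_pos = [i for i in range(len(structure)) if pt[i] > i]
    unpaired = [i for i in range(len(structure)) if pt[i] < 0]

    cols = decompose_cbc_matrix(config.planted_cbc)
    if len(cols) > len(open_pos):
        d = config.planted_cbc
        a, b = np.unravel_index(int(np.argmax(d)), d.shape)
        raise InfeasibleCBCError(
            f"planted matrix needs {len(cols)} pair columns but the scaffold "
            f"has {len(open_pos)}; largest request is between ribotypes "
            f"{a + 1} and {b + 1}"
        )

    # ancestral sequence: random canonical Watson-Crick pairs, random loops
    seq = [""] * len(structure)
    for i in unpaired:
        seq[i] = "ACGU"[rng.integers(4)]
    ancestral_state: dict[int, int] = {}
    for i in open_pos:
        state = int(rng.integers(len(_PAIR_CLIQUE)))
        ancestral_state[i] = state
        seq[i], seq[pt[i]] = _PAIR_CLIQUE[state]

    # assign planted columns to distinct pair positions
    chosen = rng.choice(len(open_pos), size=len(cols), replace=False)
    templates: list[list[str]] = []
    for r in range(config.n_ribotypes):
        t = list(seq)
        for col_idx, assign in zip(chosen, cols):
            i = open_pos[col_idx]
            state = (ancestral_state[i] + assign[r]) % len(_PAIR_CLIQUE)
            t[i], t[pt[i]] = _PAIR_CLIQUE[state]
        templates.append(t)

    records: list[StructuredSequence] = []
    truth = PlantedTruth(cbc_matrix=config.planted_cbc.copy())
    truth.notes["snp_placement"] = (
        "within-ribotype substitutions restricted to unpaired positions"
    )
    for r in range(config.n_ribotypes):
        for s in range(config.strains_per_ribotype):
            sid = f"R{r + 1}S{s + 1}"
            t = list(templates[r])
            if s > 0 and config.intra_snps > 0:
                n_snp = int(rng.integers(1, config.intra_snps + 1))
                for i in rng.choice(unpaired, size=n_snp, replace=False):
                    t[i] = rng.choice([c for c in "ACGU" if c != t[i]])
            records.append(StructuredSequence(sid, "".join(t), structure))
            truth.ribotype_of_strain[sid] = f"RIB{r + 1}"
    return records, truth


# ---------------------------------------------------------------------------
# k-mer profiles


def _random_canonical_kmers(rng: np.random.Generator, n: int, k: int) -> list[str]:
    letters = np.array(list("ACGT"))
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        block = letters[rng.integers(0, 4, size=(n - len(out) + 16, k))]
        for row in block:
            w = canonical("".join(row))
            if w not in seen:
                seen.add(w)
                out.append(w)
                if len(out) == n:
                    break
    return out


def gen_kmer_profiles(config: SynthConfig) -> tuple[list[KmerProfile], PlantedTruth]:
    """Per-strain canonical k-mer sets with a ribotype-private core.

    Each ribotype owns a private ordered core pool; a strain takes the
    first ``kmer_core_fraction`` of its profile from that pool (so the core
    is shared exactly within a ribotype) and fills the rest with a private
    draw from a global background pool.  At fraction 1 the profiles within
    a ribotype are identical; at fraction 0 no ribotype signal remains.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    size = config.kmer_profile_size
    n_core = round(config.kmer_core_fraction * size)
    if n_core > config.kmer_core_pool_size:
        raise ValueError("core pool too small for requested profile size")
    if size - n_core > config.kmer_background_pool_size:
        raise ValueError("background pool too small for requested profile size")

    total = config.n_ribotypes * config.kmer_core_pool_size + config.kmer_background_pool_size
    pool = _random_canonical_kmers(rng, total, config.kmer_k)
    core_pools = [
        pool[r * config.kmer_core_pool_size:(r + 1) * config.kmer_core_pool_size]
        for r in range(config.n_ribotypes)
    ]
    background = np.array(pool[config.n_ribotypes * config.kmer_core_pool_size:])

    profiles: list[KmerProfile] = []
    truth = PlantedTruth()
    for r in range(config.n_ribotypes):
        core = frozenset(core_pools[r][:n_core])
        for s in range(config.strains_per_ribotype):
            sid = f"R{r + 1}S{s + 1}"
            extra = rng.choice(background, size=size - n_core, replace=False)
            profiles.append(KmerProfile(sid, core | set(extra.tolist()), config.kmer_k))
            truth.ribotype_of_strain[sid] = f"RIB{r + 1}"
    return profiles, truth


# ---------------------------------------------------------------------------
# coverage tables


def gen_coverage_table(config: SynthConfig, flagged_fraction: float = 0.2,
                       noise: bool = True):
    """Coverage table with planted operon copies and a single-copy panel.

    Per strain: 7-55 genes flagged ``ok`` with Poisson coverage around the
    configured depth over aligned regions of 300-1500 bp, a configurable
    fraction of extra genes flagged ``multi_copy``/``no_hit``, and one
    operon row whose coverage is depth times the planted copy number.
    With ``noise=False`` coverages equal their expectations exactly.
    """
    from .operons import CoverageTable

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    truth = PlantedTruth()
    if config.planted_copies is not None:
        copies_of = dict(config.planted_copies)
        strains = list(copies_of)
    else:
        strains = config.strain_ids
        lo, hi = config.copies_range
        copies_of = {s: int(rng.integers(lo, hi + 1)) for s in strains}
    rows = []
    depth = config.coverage_depth
    rib_of = {s: f"RIB{i // config.strains_per_ribotype + 1}"
              for i, s in enumerate(config.strain_ids)}
    for strain in strains:
        truth.copies_of_strain[strain] = copies_of[strain]
        if strain in rib_of:
            truth.ribotype_of_strain[strain] = rib_of[strain]
        n_ok = int(rng.integers(7, 56))
        n_flagged = int(round(flagged_fraction * n_ok))
        for g in range(n_ok):
            length = int(rng.integers(300, 1501))
            cov = rng.poisson(depth * length) / length if noise else depth
            rows.append({"strain": strain, "feature": f"gene{g + 1:03d}",
                         "flag": "ok", "mean_coverage": float(cov)})
        for g in range(n_flagged):
            if rng.random() < 0.5:
                mult = float(rng.uniform(2.0, 5.0))
                cov = rng.poisson(depth * mult * 500) / 500 if noise else depth * mult
                flag = "multi_copy"
            else:
                cov, flag = 0.0, "no_hit"
            rows.append({"strain": strain, "feature": f"flagged{g + 1:03d}",
                         "flag": flag, "mean_coverage": float(cov)})
        op_len = 4000
        exp = depth * copies_of[strain]
        cov = rng.poisson(exp * op_len) / op_len if noise else exp
        rows.append({"strain": strain, "feature": "operon", "flag": "ok",
                     "mean_coverage": float(cov)})
    return CoverageTable(pd.DataFrame(rows)), truth


# ---------------------------------------------------------------------------
# community time series and environment


def _environment(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Smooth per-year descriptor trajectories over the sampling dates."""
    per_year = config.n_samples // config.n_years
    remainder = config.n_samples - per_year * config.n_years
    frames = []
    for y in range(config.n_years):
        ns = per_year + (1 if y < remainder else 0)
        start = pd.Timestamp(year=2010 + y, month=5, day=25)
        dates = start + pd.to_timedelta(2 * np.arange(ns), unit="D")
        g = np.linspace(0.0, 1.0, ns)  # within-season progression
        yoff = rng.normal(0.0, 1.0)
        env = pd.DataFrame({
            "temperature": 12.0 + 6.0 * g + yoff + rng.normal(0, 0.3, ns),
            "salinity": 34.0 - 2.5 * g + 0.3 * yoff + rng.normal(0, 0.15, ns),
            "precipitation": np.clip(
                6.0 * (1.0 - g) + np.cumsum(rng.normal(0, 0.5, ns)), 0.0, None),
            "tide_coefficient": 70.0 + 35.0 * np.sin(
                2 * np.pi * np.arange(ns) * 2.0 / 14.0 + rng.uniform(0, 2 * np.pi)),
            "NO3": np.clip(20.0 * (1.0 - g) + 2.0 * yoff + rng.normal(0, 1.0, ns), 0.1, None),
            "PO4": np.clip(1.2 - 0.8 * g + 0.1 * yoff + rng.normal(0, 0.08, ns), 0.02, None),
            "SiOH4": np.clip(9.0 - 4.0 * g + rng.normal(0, 0.6, ns), 0.2, None),
        }, index=dates)
        env["year"] = 2010 + y
        frames.append(env)
    return pd.concat(frames)


def gen_community_series(config: SynthConfig):
    """Sample x taxon counts, environment table, and planted niche truth.

    Expected counts follow Gaussian niche responses in range-standardized
    descriptor space: ``E[count] = A exp(-||x_i - mu_s||^2 / (2 sigma_s^2))``,
    realized as Poisson draws.  The first ``n_ribotypes`` taxa are the
    parasite ribotypes (they carry operon copy numbers and host-range
    classes downstream); the rest are free-living background taxa.  Planted
    optima sit on the realized environmental trajectory so each taxon
    prefers a specific phase of the seasonal gradient.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    env = _environment(config, rng)
    years = env.pop("year")
    x = env.to_numpy(dtype=float)
    xs = (x - x.min(axis=0)) / (x.max(axis=0) - x.min(axis=0))

    n_taxa = config.n_taxa
    taxa = [f"RIB{r + 1}" for r in range(min(config.n_ribotypes, n_taxa))]
    taxa += [f"TAX{t + 1}" for t in range(n_taxa - len(taxa))]

    if config.niche_optima is not None:
        optima = np.asarray(config.niche_optima, dtype=float)
        if optima.shape != (n_taxa, xs.shape[1]):
            raise ValueError("niche_optima shape must be (n_taxa, 7)")
    else:
        # anchor optima on realized conditions at staggered sampling phases
        anchors = np.linspace(0, len(xs) - 1, n_taxa).astype(int)
        perm = rng.permutation(n_taxa)
        optima = xs[anchors[perm]] + rng.normal(0.0, 0.02, size=(n_taxa, xs.shape[1]))
    breadth = np.broadcast_to(np.asarray(config.niche_breadth, dtype=float),
                              (n_taxa,)).copy()

    sq = ((xs[:, None, :] - optima[None, :, :]) ** 2).sum(axis=2)
    lam = config.niche_amplitude * np.exp(-sq / (2.0 * breadth[None, :] ** 2))
    counts = rng.poisson(lam)
    community = pd.DataFrame(counts, index=env.index, columns=taxa)

    truth = PlantedTruth(optima=optima, breadth=breadth, taxa=taxa)
    truth.notes["standardization"] = "optima live in range-standardized descriptor space"
    return community, env, years, truth


# ---------------------------------------------------------------------------
# host range and phenotypes


DEFAULT_HOST_CLASSES = {
    "RIB1": 1, "RIB2": 4, "RIB3": 1, "RIB4": 5, "RIB5": 3, "RIB6": 1,
    "RIB7": 1, "RIB8": 3,
}


def gen_host_phenotype_tables(config: SynthConfig,
                              host_classes: dict[str, int] | None = None,
                              strains_per_host_species: int = 2):
    """Cross-infection presence/absence matrix and cytometry phenotypes.

    Strains of one ribotype share a host set: every parasite infects all
    strains of the universal host species, and a ribotype of host-range
    class ``n`` infects the first ``n`` host species.  Phenotype values
    (FSC, SSC, green fluorescence, fluorescence ratio to the 1C reference)
    scatter around ribotype-level means; one ribotype group is brighter and
    larger, mirroring a higher-clade signature, and genome-size ratios fall
    in two groups.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    if host_classes is None:
        host_classes = {f"RIB{r + 1}": DEFAULT_HOST_CLASSES.get(f"RIB{r + 1}", 1)
                        for r in range(config.n_ribotypes)}
    host_strains = [f"{sp}_h{i + 1}" for sp in HOST_SPECIES
                    for i in range(strains_per_host_species)]
    species_of_host = {h: h.rsplit("_h", 1)[0] for h in host_strains}

    rows = {}
    pheno_rows = []
    truth = PlantedTruth()
    for r in range(config.n_ribotypes):
        rib = f"RIB{r + 1}"
        n_hosts = host_classes[rib]
        sensitive = set(HOST_SPECIES[:n_hosts])
        truth.host_class_of_ribotype[rib] = str(n_hosts)
        bright = rib in ("RIB2",)
        big_genome = rib in ("RIB2", "RIB5", "RIB6")
        for s in range(config.strains_per_ribotype):
            sid = f"R{r + 1}S{s + 1}"
            truth.ribotype_of_strain[sid] = rib
            rows[sid] = [1 if species_of_host[h] in sensitive else 0
                         for h in host_strains]
            fsc = rng.lognormal(np.log(5e4 if bright else 2e4), 0.15)
            ssc = rng.lognormal(np.log(3e4 if bright else 1.2e4), 0.15)
            green = rng.lognormal(np.log(8e3 if bright else 3e3), 0.2)
            ratio = rng.normal(10.5 if big_genome else 6.5, 0.35)
            pheno_rows.append({"strain": sid, "ribotype": rib, "FSC": fsc,
                               "SSC": ssc, "green_fluorescence": green,
                               "fluorescence_ratio": max(ratio, 0.5)})
    host_matrix = pd.DataFrame.from_dict(rows, orient="index", columns=host_strains)
    phenotypes = pd.DataFrame(pheno_rows).set_index("strain")
    return phenotypes, host_matrix, species_of_host, truth
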