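"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is a pure function of its scenario and an integer seed,
so each downstream stage can be tested at desk scale with no external
download: bait-anchored 4C counts with power-law distance decay plus
planted associating domains, gene placement with compartment-dependent
density, a five-condition irradiation expression course with four
planted kinetic clusters, and IP/input ChIP tracks with
compartment-dependent temporal dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fragment_map import FragmentMap
from .fourc_domains import SiteProfile
from .spatial_integration import BinnedChipTrack

CONDITIONS = ("0h", "1Gy-6h", "1Gy-24h", "6Gy-6h", "6Gy-24h")
CHIP_TIMEPOINTS = ("0h", "3h", "24h")
COMPARTMENTS = ("active", "facultative_het")

# Condition-wise log2 fold changes of the four kinetic classes:
# 1 = down at both 6Gy conditions (dose-dependent early repression),
# 2 = down at both 24 h conditions, 3 = up at 6Gy-24h only,
# 4 = up at both 24 h conditions.
DEFAULT_CLUSTER_PROFILES: dict[int, tuple[float, ...]] = {
    1: (0.0, 0.0, 0.0, -2.0, -2.0),
    2: (0.0, 0.0, -2.0, 0.0, -2.0),
    3: (0.0, 0.0, 0.0, 0.0, 2.0),
    4: (0.0, 0.0, 2.0, 0.0, 2.0),
}

# IP/input multipliers per compartment and timepoint: active chromatin
# repairs early (up at 3 h, depleted at 24 h), facultative
# heterochromatin late (low at 3 h, increased at 24 h).
DEFAULT_CHIP_DYNAMICS: dict[str, dict[str, float]] = {
    "active": {"0h": 1.0, "3h": 2.0, "24h": 0.8},
    "facultative_het": {"0h": 1.0, "3h": 0.9, "24h": 1.5},
}

_SALT = {"fragmap": 11, "fourc": 13, "genes": 17, "expression": 19, "chip": 23}


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedDomain:
    chrom: str
    start: int
    end: int
    fold_enrichment: float
    compartment: str = "active"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ScenarioError(f"domain {self} has start >= end")
        if self.fold_enrichment <= 0:
            raise ScenarioError("fold_enrichment must be strictly positive")
        if self.compartment not in COMPARTMENTS:
            raise ScenarioError(
                f"unknown compartment {self.compartment!r}; "
                f"expected one of {COMPARTMENTS}"
            )


@dataclass(frozen=True)
class SyntheticScenario:
    """Full parameterization of the synthetic inputs.

    The default genome is 2 chromosomes x 20 Mb with ~4 kb expected site
    spacing so the whole pipeline runs in seconds.
    """

    seed: int = 0
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 20_000_000, "chr2": 20_000_000}
    )
    site_spacing_bp: float = 4096.0
    bait_id: str = "bait1"
    bait_chrom: str = "chr1"
    bait_pos: int = 10_000_000
    cis_domains: tuple[PlantedDomain, ...] = ()
    trans_domains: tuple[PlantedDomain, ...] = ()
    decay_exponent: float = 1.0
    background_rate: float = 20.0
    trans_rate: float = 0.5
    nb_dispersion: float = 0.1
    min_distance_bp: int = 2000
    n_genes: int = 2000
    gene_length_bp: int = 10_000
    gene_density_ratio: float = 1.0
    cluster_proportions: Mapping[object, float] = field(
        default_factory=lambda: {
            1: 0.05, 2: 0.05, 3: 0.05, 4: 0.05, "stable": 0.8
        }
    )
    cluster_active_bias: Mapping[object, float] = field(default_factory=dict)
    cluster_profiles: Mapping[int, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_CLUSTER_PROFILES)
    )
    baseline_expression: float = 200.0
    expression_dispersion: float = 0.05
    n_replicates: int = 3
    chip_bin_bp: int = 10_000
    chip_input_rate: float = 50.0
    chip_dynamics: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_CHIP_DYNAMICS.items()
        }
    )

    def __post_init__(self) -> None:
        for name in ("background_rate", "trans_rate", "nb_dispersion",
                     "baseline_expression", "expression_dispersion",
                     "chip_input_rate", "gene_density_ratio"):
            if getattr(self, name) <= 0:
                raise ScenarioError(f"{name} must be strictly positive")
        if self.bait_chrom not in self.chrom_lengths:
            raise ScenarioError(f"bait chromosome {self.bait_chrom!r} unknown")
        for dom in self.cis_domains:
            if dom.chrom != self.bait_chrom:
                raise ScenarioError("cis domains must lie on the bait chromosome")
        for dom in self.trans_domains:
            if dom.chrom == self.bait_chrom:
                raise ScenarioError("trans domains must avoid the bait chromosome")
        for dom in self.cis_domains + self.trans_domains:
            if dom.chrom not in self.chrom_lengths:
                raise ScenarioError(f"domain chromosome {dom.chrom!r} unknown")
            if dom.end > self.chrom_lengths[dom.chrom]:
                raise ScenarioError(f"domain {dom} exceeds chromosome bounds")
        _check_no_overlap(self.cis_domains + self.trans_domains)
        for label, profile in self.cluster_profiles.items():
            if len(profile) != len(CONDITIONS):
                raise ScenarioError(
                    f"cluster {label} profile must have {len(CONDITIONS)} "
                    f"entries, got {len(profile)}"
                )
        for comp in self.chip_dynamics:
            if comp not in COMPARTMENTS:
                raise ScenarioError(f"unknown compartment label {comp!r}")

    @property
    def planted_domains(self) -> tuple[PlantedDomain, ...]:
        return self.cis_domains + self.trans_domains

    def rng(self, stage: str, seed: int | None = None) -> np.random.Generator:
        base = self.seed if seed is None else seed
        return np.random.default_rng([_SALT[stage], base])


def _check_no_overlap(domains: Sequence[PlantedDomain]) -> None:
    by_chrom: dict[str, list[PlantedDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append(d)
    for chrom, ds in by_chrom.items():
        ds = sorted(ds, key=lambda d: d.start)
        for a, b in zip(ds[:-1], ds[1:]):
            if b.start < a.end:
                raise ScenarioError(f"planted domains overlap on {chrom}")


def default_scenario(
    seed: int = 0,
    n_domain_sites: int = 30,
    cis_fold: float = 5.0,
    trans_fold: float = 8.0,
    **overrides,
) -> SyntheticScenario:
    """Desk-scale scenario with planted domains snapped to the site grid.

    Domain boundaries are placed on the realized cut-site grid of the
    scenario's own fragment map so each planted domain spans exactly
    ``n_domain_sites`` sites regardless of spacing fluctuations.
    """
    params = dict(seed=seed)
    params.update(
        {k: v for k, v in overrides.items()
         if k not in ("cis_domains", "trans_domains")}
    )
    base = SyntheticScenario(**params)
    fragmap = simulate_fragment_map(base)

    def span(chrom: str, anchor: int) -> tuple[int, int]:
        pos = fragmap.site_positions[chrom]
        i = int(np.searchsorted(pos, anchor))
        i = min(max(i, 0), len(pos) - n_domain_sites - 1)
        return int(pos[i]), int(pos[i + n_domain_sites])

    bait = base.bait_pos
    cis = overrides.get("cis_domains")
    if cis is None:
        cis = tuple(
            PlantedDomain(
                base.bait_chrom, *span(base.bait_chrom, bait + off),
                cis_fold,
                "active" if i % 2 == 0 else "facultative_het",
            )
            for i, off in enumerate(
                (-4_000_000, -2_000_000, 1_500_000, 3_000_000)
            )
        )
    trans = overrides.get("trans_domains")
    if trans is None:
        trans_chrom = next(
            (c for c in base.chrom_lengths if c != base.bait_chrom), None
        )
        trans = ()
        if trans_chrom is not None:
            trans = (
                PlantedDomain(
                    trans_chrom, *span(trans_chrom, 5_000_000),
                    trans_fold, "active",
                ),
                PlantedDomain(
                    trans_chrom, *span(trans_chrom, 12_000_000),
                    trans_fold, "facultative_het",
                ),
            )
    return replace(base, cis_domains=tuple(cis), trans_domains=tuple(trans))


# ---------------------------------------------------------------------
# fragment map / genome
# ---------------------------------------------------------------------


def simulate_fragment_map(
    scenario: SyntheticScenario, seed: int | None = None
) -> FragmentMap:
    """Cut-site grid with exponential spacing (Poisson motif process)."""
    rng = scenario.rng("fragmap", seed)
    chrom_lengths: dict[str, int] = {}
    fragments: dict[str, np.ndarray] = {}
    site_positions: dict[str, np.ndarray] = {}
    for chrom, length in scenario.chrom_lengths.items():
        n_draw = int(length / scenario.site_spacing_bp * 1.5) + 16
        gaps = rng.exponential(scenario.site_spacing_bp, n_draw)
        pos = np.cumsum(gaps).astype(np.int64)
        pos = np.unique(pos[(pos > 0) & (pos < length)])
        bounds = np.concatenate(([0], pos, [length]))
        chrom_lengths[chrom] = length
        fragments[chrom] = np.column_stack((bounds[:-1], bounds[1:]))
        site_positions[chrom] = pos
    return FragmentMap(chrom_lengths, fragments, site_positions)


def random_genome(
    scenario: SyntheticScenario, seed: int | None = None
) -> dict[str, str]:
    """I.i.d. uniform ACGT sequences of the scenario's chromosomes."""
    rng = scenario.rng("fragmap", seed)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return {
        chrom: rng.choice(alphabet, size=length).tobytes().decode("ascii")
        for chrom, length in scenario.chrom_lengths.items()
    }


# ---------------------------------------------------------------------
# 4C counts
# ---------------------------------------------------------------------


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    r = 1.0 / dispersion
    p = r / (r + np.asarray(mean, dtype=float))
    return rng.negative_binomial(r, p)


def expected_4c_mean(
    scenario: SyntheticScenario,
    fragmap: FragmentMap,
    with_domains: bool = True,
) -> np.ndarray:
    """Model mean count per site in global site order."""
    mu = np.empty(fragmap.n_sites(), dtype=float)
    for chrom in fragmap.chroms:
        sl = fragmap.site_slice(chrom)
        pos = fragmap.site_positions[chrom]
        if chrom == scenario.bait_chrom:
            d = np.maximum(
                np.abs(pos - scenario.bait_pos), scenario.min_distance_bp
            )
            mu[sl] = scenario.background_rate * (d / 1e5) ** (
                -scenario.decay_exponent
            )
        else:
            mu[sl] = scenario.trans_rate
    if with_domains:
        for dom in scenario.planted_domains:
            sl = fragmap.site_slice(dom.chrom)
            pos = fragmap.site_positions[dom.chrom]
            m = (pos >= dom.start) & (pos < dom.end)
            mu[sl.start : sl.stop][m] *= dom.fold_enrichment
    return mu


def _bait_adjacent_indices(
    scenario: SyntheticScenario, fragmap: FragmentMap
) -> np.ndarray:
    sl = fragmap.site_slice(scenario.bait_chrom)
    pos = fragmap.site_positions[scenario.bait_chrom]
    i = int(np.searchsorted(pos, scenario.bait_pos))
    idx = [j for j in (i - 1, i) if 0 <= j < len(pos)]
    return np.asarray(idx, dtype=np.int64) + sl.start


def simulate_4c_counts(
    scenario: SyntheticScenario,
    fragmap: FragmentMap,
    seed: int | None = None,
    conditions: Sequence[str] = CONDITIONS,
) -> dict[str, SiteProfile]:
    """Negative-binomial per-site counts for every condition.

    Cis means follow a power-law decay from the bait; trans means are a
    low uniform rate; planted domains multiply the mean by their fold
    enrichment.  The two bait-adjacent sites are zeroed (self-ligation
    blind spot).  Planted domains must span at least 20 sites of the
    grid.
    """
    _validate_domains_against_map(scenario, fragmap)
    rng = scenario.rng("fourc", seed)
    mu = expected_4c_mean(scenario, fragmap)
    blind = _bait_adjacent_indices(scenario, fragmap)
    profiles = {}
    for condition in conditions:
        counts = _nb_draw(rng, mu, scenario.nb_dispersion)
        counts[blind] = 0
        profiles[condition] = SiteProfile(
            bait_id=scenario.bait_id,
            bait_chrom=scenario.bait_chrom,
            bait_pos=scenario.bait_pos,
            condition=condition,
            counts=counts,
        )
    return profiles


def _validate_domains_against_map(
    scenario: SyntheticScenario, fragmap: FragmentMap, min_sites: int = 20
) -> None:
    for dom in scenario.planted_domains:
        if dom.chrom not in fragmap.chrom_lengths:
            raise ScenarioError(f"domain chromosome {dom.chrom!r} not in map")
        if dom.end > fragmap.chrom_lengths[dom.chrom]:
            raise ScenarioError(f"domain {dom} outside chromosome bounds")
        pos = fragmap.site_positions[dom.chrom]
        n = int(np.sum((pos >= dom.start) & (pos < dom.end)))
        if n < min_sites:
            raise ScenarioError(
                f"domain {dom.chrom}:{dom.start}-{dom.end} spans only "
                f"{n} sites (< {min_sites})"
            )


# ---------------------------------------------------------------------
# genes
# ---------------------------------------------------------------------


def compartment_union(
    scenario: SyntheticScenario, compartment: str | None = None
) -> list[tuple[str, int, int]]:
    doms = scenario.planted_domains
    if compartment is not None:
        doms = tuple(d for d in doms if d.compartment == compartment)
    return [(d.chrom, d.start, d.end) for d in doms]


def simulate_genes(
    scenario: SyntheticScenario, fragmap: FragmentMap, seed: int | None = None
) -> pd.DataFrame:
    """Gene table with TSSs from an inhomogeneous Poisson placement.

    The placement rate inside planted active-compartment domains is
    ``gene_density_ratio`` times the outside rate.  Genes get a fixed
    body length, random strand, and a cluster label (1-4 or "stable")
    drawn from the scenario proportions, optionally reweighted inside
    active domains by ``cluster_active_bias``.
    """
    rng = scenario.rng("genes", seed)
    n = scenario.n_genes
    if n == 0:
        return add_tss_columns(
            pd.DataFrame(
                columns=["gene_id", "chrom", "start", "end", "strand", "cluster"]
            )
        )

    # piecewise-constant placement density over each chromosome
    active = {
        d.chrom: [] for d in scenario.planted_domains
    }
    for d in scenario.planted_domains:
        if d.compartment == "active":
            active.setdefault(d.chrom, []).append((d.start, d.end))
    segments = []  # (chrom, start, end, weight)
    for chrom, length in scenario.chrom_lengths.items():
        cuts = sorted(
            {0, length}
            | {s for s, _ in active.get(chrom, [])}
            | {e for _, e in active.get(chrom, [])}
        )
        for a, b in zip(cuts[:-1], cuts[1:]):
            inside = any(s <= a and b <= e for s, e in active.get(chrom, []))
            w = scenario.gene_density_ratio if inside else 1.0
            segments.append((chrom, a, b, w * (b - a)))
    weights = np.asarray([s[3] for s in segments], dtype=float)
    weights /= weights.sum()
    seg_idx = rng.choice(len(segments), size=n, p=weights)
    tss = np.empty(n, dtype=np.int64)
    chroms = np.empty(n, dtype=object)
    for i, j in enumerate(seg_idx):
        chrom, a, b, _ = segments[j]
        chroms[i] = chrom
        tss[i] = rng.integers(a, b)

    strand = rng.choice(np.array(["+", "-"]), size=n)
    start = np.where(
        strand == "+", tss, tss - (scenario.gene_length_bp - 1)
    )
    lengths = np.asarray(
        [scenario.chrom_lengths[c] for c in chroms], dtype=np.int64
    )
    start = np.clip(start, 0, None)
    end = np.minimum(start + scenario.gene_length_bp, lengths)

    labels = list(scenario.cluster_proportions)
    base_p = np.asarray(
        [scenario.cluster_proportions[l] for l in labels], dtype=float
    )
    base_p /= base_p.sum()
    bias = np.asarray(
        [scenario.cluster_active_bias.get(l, 1.0) for l in labels], dtype=float
    )
    from .spatial_integration import merge_intervals, points_in_union

    union = merge_intervals(compartment_union(scenario, "active"))
    in_active = points_in_union(chroms, tss, union)
    cluster = np.empty(n, dtype=object)
    p_in = base_p * bias
    p_in /= p_in.sum()
    for i in range(n):
        p = p_in if in_active[i] else base_p
        cluster[i] = labels[rng.choice(len(labels), p=p)]

    genes = pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(n)],
            "chrom": chroms,
            "start": start,
            "end": end,
            "strand": strand,
            "cluster": cluster,
        }
    )
    return add_tss_columns(genes)


def add_tss_columns(genes: pd.DataFrame) -> pd.DataFrame:
    from .spatial_integration import add_tss

    if len(genes) == 0:
        genes = genes.copy()
        genes["tss"] = pd.Series(dtype=np.int64)
        return genes
    return add_tss(genes)


# ---------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------


def sample_sheet(scenario: SyntheticScenario) -> pd.DataFrame:
    rows = [
        {
            "sample": f"{cond}_r{r + 1}",
            "condition": cond,
            "replicate": r + 1,
        }
        for cond in CONDITIONS
        for r in range(scenario.n_replicates)
    ]
    return pd.DataFrame(rows)


def simulate_expression(
    scenario: SyntheticScenario,
    genes: pd.DataFrame,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw negative-binomial count matrix over the five conditions.

    Returns ``(counts, samples)``: counts indexed by gene_id with one
    column per sample; the mean of gene g in condition j is
    ``baseline * 2**profile[cluster(g)][j]`` ("stable" genes are flat).
    """
    for label, profile in scenario.cluster_profiles.items():
        if len(profile) != len(CONDITIONS):
            raise ScenarioError("cluster profile length must equal 5")
    rng = scenario.rng("expression", seed)
    samples = sample_sheet(scenario)
    logfc = np.zeros((len(genes), len(CONDITIONS)), dtype=float)
    for label, profile in scenario.cluster_profiles.items():
        m = (genes["cluster"] == label).to_numpy()
        if m.any():
            logfc[m] = np.asarray(profile, dtype=float)
    mean = scenario.baseline_expression * 2.0 ** logfc
    data = {}
    for _, row in samples.iterrows():
        j = CONDITIONS.index(row["condition"])
        data[row["sample"]] = _nb_draw(
            rng, mean[:, j], scenario.expression_dispersion
        )
    counts = pd.DataFrame(data, index=genes["gene_id"].to_numpy())
    counts.index.name = "gene_id"
    return counts, samples


# ---------------------------------------------------------------------
# ChIP
# ---------------------------------------------------------------------


def bin_grid(scenario: SyntheticScenario) -> pd.DataFrame:
    rows = []
    for chrom, length in scenario.chrom_lengths.items():
        starts = np.arange(0, length, scenario.chip_bin_bp)
        ends = np.minimum(starts + scenario.chip_bin_bp, length)
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def simulate_chip(
    scenario: SyntheticScenario,
    fragmap: FragmentMap | None = None,
    seed: int | None = None,
    timepoints: Sequence[str] = CHIP_TIMEPOINTS,
) -> dict[str, BinnedChipTrack]:
    """Poisson IP/input tracks with compartment-dependent dynamics.

    Input counts are uniform Poisson per bin; IP counts are Poisson with
    the input mean times the compartment multiplier of the timepoint
    (bins outside any planted domain have multiplier 1).  Compartment
    membership is decided by bin midpoint.
    """
    for comp in {d.compartment for d in scenario.planted_domains}:
        if comp not in scenario.chip_dynamics:
            raise ScenarioError(
                f"no chip_dynamics for compartment {comp!r}"
            )
    rng = scenario.rng("chip", seed)
    bins = bin_grid(scenario)
    mid = ((bins["start"] + bins["end"]) // 2).to_numpy()
    chroms = bins["chrom"].to_numpy()
    from .spatial_integration import merge_intervals, points_in_union

    comp_of_bin = np.full(len(bins), "", dtype=object)
    for comp in COMPARTMENTS:
        union = merge_intervals(compartment_union(scenario, comp))
        inside = points_in_union(chroms, mid, union)
        comp_of_bin[inside] = comp

    tracks = {}
    for tp in timepoints:
        mult = np.ones(len(bins), dtype=float)
        for comp in COMPARTMENTS:
            dyn = scenario.chip_dynamics.get(comp)
            if dyn is None:
                continue
            if tp not in dyn:
                raise ScenarioError(
                    f"chip_dynamics[{comp!r}] missing timepoint {tp!r}"
                )
            mult[comp_of_bin == comp] = dyn[tp]
        input_counts = rng.poisson(scenario.chip_input_rate, len(bins))
        ip_counts = rng.poisson(scenario.chip_input_rate * mult)
        tracks[tp] = BinnedChipTrack(
            bins=bins.copy(),
            ip=ip_counts,
            input_=input_counts,
            timepoint=tp,
        )
    return tracks
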