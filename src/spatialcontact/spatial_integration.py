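"""Integrative readouts over called contact domains.

Three quantities are computed on a domain set: gene density (genes per
Mb of the domain union vs genome-wide), relative enrichment of
expression clusters among the genes whose TSS falls in the union, and
the ChIP IP/input signal ratio of the union per timepoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


class IntegrationError(ValueError):
    pass


@dataclass
class BinnedChipTrack:
    """IP and input read counts on a fixed-width bin grid.

    ``bins`` has columns chrom/start/end tiling the genome; ``ip`` and
    ``input_`` are aligned count vectors.
    """

    bins: pd.DataFrame
    ip: np.ndarray
    input_: np.ndarray
    timepoint: str
    ip_library_size: int = 0
    input_library_size: int = 0

    def __post_init__(self) -> None:
        self.ip = np.asarray(self.ip, dtype=np.int64)
        self.input_ = np.asarray(self.input_, dtype=np.int64)
        if len(self.ip) != len(self.bins) or len(self.input_) != len(self.bins):
            raise ValueError("ip/input length must match the bin grid")
        if np.any(self.ip < 0) or np.any(self.input_ < 0):
            raise ValueError("counts must be non-negative")
        if self.ip_library_size == 0:
            self.ip_library_size = int(self.ip.sum())
        if self.input_library_size == 0:
            self.input_library_size = int(self.input_.sum())


# ---------------------------------------------------------------------
# interval helpers
# ---------------------------------------------------------------------


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]]
) -> dict[str, np.ndarray]:
    """Union of half-open intervals, merged per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if start >= end:
            continue
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    out: dict[str, np.ndarray] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.asarray(merged, dtype=np.int64)
    return out


def union_length(union: Mapping[str, np.ndarray]) -> int:
    return int(
        sum((arr[:, 1] - arr[:, 0]).sum() for arr in union.values())
    )


def points_in_union(
    chroms: Sequence[str], positions: np.ndarray, union: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Boolean membership of (chrom, pos) points in a half-open union."""
    positions = np.asarray(positions)
    inside = np.zeros(len(positions), dtype=bool)
    chrom_arr = np.asarray(chroms, dtype=object)
    for chrom, ivs in union.items():
        m = chrom_arr == chrom
        if not m.any():
            continue
        pos = positions[m]
        idx = np.searchsorted(ivs[:, 0], pos, side="right") - 1
        ok = (idx >= 0) & (pos < ivs[np.clip(idx, 0, None), 1])
        inside[m] = ok
    return inside


def domains_to_intervals(domains) -> list[tuple[str, int, int]]:
    """Half-open intervals from a domain iterable or BED-like frame."""
    if isinstance(domains, pd.DataFrame):
        return [
            (str(r.chrom), int(r.start), int(r.end))
            for r in domains.itertuples()
        ]
    out = []
    for d in getattr(domains, "domains", domains):
        out.append((d.chrom, int(d.start), int(d.end)))
    return out


# ---------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------


def add_tss(genes: pd.DataFrame) -> pd.DataFrame:
    """Annotate a gene table with its TSS (start on +, end-1 on −)."""
    genes = genes.copy()
    if not set(GENE_COLUMNS) <= set(genes.columns):
        missing = set(GENE_COLUMNS) - set(genes.columns)
        raise IntegrationError(f"gene table missing columns {missing}")
    bad = genes[genes["start"] >= genes["end"]]
    if len(bad):
        raise IntegrationError(
            f"genes with start >= end: {list(bad['gene_id'].head())}"
        )
    if not genes["strand"].isin(["+", "-"]).all():
        raise IntegrationError("strand must be '+' or '-'")
    genes["tss"] = np.where(
        genes["strand"] == "+", genes["start"], genes["end"] - 1
    )
    return genes


# ---------------------------------------------------------------------
# readouts
# ---------------------------------------------------------------------


class GeneDensity(NamedTuple):
    density_in_domains: float  # genes per Mb; NaN when no domains
    density_genome: float


def gene_density(
    domains, genes: pd.DataFrame, genome_size_bp: int
) -> GeneDensity:
    """Genes per Mb inside the domain union and genome-wide.

    Membership is by TSS containment.  With an empty domain set the
    in-domain density is undefined and reported as NaN.
    """
    if genome_size_bp <= 0:
        raise IntegrationError("genome_size_bp must be positive")
    genes = genes if "tss" in genes.columns else add_tss(genes)
    n_total = len(genes)
    density_genome = n_total / (genome_size_bp / 1e6)
    union = merge_intervals(domains_to_intervals(domains))
    length = union_length(union)
    if length == 0:
        return GeneDensity(math.nan, density_genome)
    if n_total == 0:
        return GeneDensity(0.0, 0.0)
    inside = points_in_union(
        genes["chrom"].to_numpy(), genes["tss"].to_numpy(), union
    )
    return GeneDensity(float(inside.sum()) / (length / 1e6), density_genome)


def cluster_enrichment(
    domains_by_bait: Mapping[str, object],
    genes: pd.DataFrame,
    clusters: Sequence[object] = (1, 2, 3, 4),
    with_pvalues: bool = True,
) -> pd.DataFrame:
    """Relative enrichment of each expression cluster per bait.

    For cluster *c* and bait *b*: the fraction of cluster-c genes whose
    TSS lies in b's domain union divided by the same fraction over the
    whole gene universe (every row of ``genes``).  Cells where no
    universe gene falls in the union are NaN.  Returns a tidy frame with
    raw and log2 enrichment plus an optional one-sided hypergeometric
    p-value for over-representation.
    """
    genes = genes if "tss" in genes.columns else add_tss(genes)
    if "cluster" not in genes.columns:
        raise IntegrationError("gene table must carry a 'cluster' column")
    n_universe = len(genes)
    rows = []
    for bait, domains in domains_by_bait.items():
        union = merge_intervals(domains_to_intervals(domains))
        inside = points_in_union(
            genes["chrom"].to_numpy(), genes["tss"].to_numpy(), union
        )
        n_in = int(inside.sum())
        frac_universe = n_in / n_universe if n_universe else 0.0
        for c in clusters:
            is_c = (genes["cluster"] == c).to_numpy()
            n_c = int(is_c.sum())
            k_c = int((is_c & inside).sum())
            if n_c == 0 or frac_universe == 0.0:
                enr = math.nan
            else:
                enr = (k_c / n_c) / frac_universe
            row = {
                "bait": bait,
                "cluster": c,
                "n_cluster": n_c,
                "n_cluster_in_domains": k_c,
                "n_universe": n_universe,
                "n_universe_in_domains": n_in,
                "enrichment": enr,
                "log2_enrichment": (
                    math.log2(enr) if enr and not math.isnan(enr) else -math.inf
                    if enr == 0.0 else math.nan
                ),
            }
            if with_pvalues:
                row["p_over"] = (
                    float(hypergeom.sf(k_c - 1, n_universe, n_in, n_c))
                    if n_c
                    else math.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)


def enrichment_matrix(tidy: pd.DataFrame, log2: bool = False) -> pd.DataFrame:
    """Pivot the tidy enrichment table to clusters × baits."""
    value = "log2_enrichment" if log2 else "enrichment"
    return tidy.pivot(index="cluster", columns="bait", values=value)


def chip_signal_in_domains(
    tracks: Mapping[str, BinnedChipTrack] | BinnedChipTrack,
    domains,
    scale_by_library: bool = True,
    min_overlap_frac: float = 0.5,
) -> pd.DataFrame:
    """IP/input signal of the domain union per timepoint.

    A bin is selected when at least ``min_overlap_frac`` of it overlaps
    the domain union.  The ratio is total IP over total input counts in
    the selected bins; with ``scale_by_library`` each side is divided by
    its library size first.
    """
    if isinstance(tracks, BinnedChipTrack):
        tracks = {tracks.timepoint: tracks}
    union = merge_intervals(domains_to_intervals(domains))
    rows = []
    for timepoint, track in tracks.items():
        bins = track.bins
        starts = bins["start"].to_numpy()
        ends = bins["end"].to_numpy()
        overlap = np.zeros(len(bins), dtype=np.int64)
        chrom_arr = bins["chrom"].to_numpy()
        for chrom, ivs in union.items():
            m = chrom_arr == chrom
            if not m.any():
                continue
            s, e = starts[m], ends[m]
            ov = np.zeros(len(s), dtype=np.int64)
            for a, b in ivs:
                ov += np.maximum(
                    np.minimum(e, b) - np.maximum(s, a), 0
                )
            overlap[m] = ov
        width = ends - starts
        selected = overlap >= min_overlap_frac * width
        ip_sum = int(track.ip[selected].sum())
        input_sum = int(track.input_[selected].sum())
        if input_sum == 0:
            raise IntegrationError(
                f"zero input signal in domain union at timepoint "
                f"{timepoint!r}"
            )
        if scale_by_library:
            ratio = (ip_sum / track.ip_library_size) / (
                input_sum / track.input_library_size
            )
        else:
            ratio = ip_sum / input_sum
        rows.append(
            {
                "timepoint": timepoint,
                "n_bins": int(selected.sum()),
                "ip_sum": ip_sum,
                "input_sum": input_sum,
                "ratio": ratio,
            }
        )
    return pd.DataFrame(rows)
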