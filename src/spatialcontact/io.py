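"""Plain-text readers and writers for the pipeline's artifact formats.

All genomic files are 0-based half-open and sorted by (chrom, start);
tables are tab-separated with a header line.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .fragment_map import FragmentMap
from .fourc_domains import ContactDomainSet, SiteProfile, WindowScoreTrack
from .spatial_integration import BinnedChipTrack


# ---------------------------------------------------------------------
# per-site counts
# ---------------------------------------------------------------------


def write_site_counts(
    profile: SiteProfile, fragmap: FragmentMap, path: str | Path
) -> None:
    chroms = fragmap.site_chroms()
    positions = fragmap.all_site_positions()
    df = pd.DataFrame(
        {"chrom": chroms, "site_pos": positions, "count": profile.counts}
    )
    df.to_csv(path, sep="\t", index=False)


def read_site_counts(
    path: str | Path,
    fragmap: FragmentMap,
    bait_id: str,
    bait_chrom: str,
    bait_pos: int,
    condition: str,
) -> SiteProfile:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "site_pos", "count"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    counts = np.zeros(fragmap.n_sites(), dtype=np.int64)
    for chrom, group in df.groupby("chrom", sort=False):
        sl = fragmap.site_slice(str(chrom))
        pos = fragmap.site_positions[str(chrom)]
        idx = np.searchsorted(pos, group["site_pos"].to_numpy())
        if np.any(idx >= len(pos)) or np.any(
            pos[np.clip(idx, 0, len(pos) - 1)] != group["site_pos"].to_numpy()
        ):
            raise ValueError(
                f"{path}: site positions on {chrom} do not match the "
                "fragment map"
            )
        counts[sl.start + idx] = group["count"].to_numpy()
    return SiteProfile(
        bait_id=bait_id,
        bait_chrom=bait_chrom,
        bait_pos=bait_pos,
        condition=condition,
        counts=counts,
    )


# ---------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------


def write_bedgraph(
    frame: pd.DataFrame, path: str | Path, value_col: str = "value"
) -> None:
    """Write chrom/start/end/value columns as bedGraph."""
    with open(path, "w") as fh:
        for row in frame.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t"
                f"{getattr(row, value_col)}\n"
            )


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
    )
    return df


def pscore_bedgraph(
    track: WindowScoreTrack, fragmap: FragmentMap
) -> pd.DataFrame:
    chroms = fragmap.site_chroms()
    pos = fragmap.all_site_positions()
    m = track.scope_mask
    return pd.DataFrame(
        {
            "chrom": chroms[m],
            "start": pos[m],
            "end": pos[m] + 1,
            "value": np.round(track.p_score[m], 4),
        }
    )


# ---------------------------------------------------------------------
# domains
# ---------------------------------------------------------------------


def write_domains_bed(
    domain_set: ContactDomainSet, path: str | Path
) -> None:
    """BED6: name = bait:condition:scope, score = mean p-score x 10."""
    frame = domain_set.to_frame()
    frame = frame.sort_values(["chrom", "start"])
    with open(path, "w") as fh:
        for row in frame.itertuples(index=False):
            score = min(int(row.score), 1000)
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t"
                f"{score}\t.\n"
            )


def read_domains_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            rows.append((chrom, start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_domain_sidecar(
    domain_set: ContactDomainSet, path: str | Path
) -> None:
    payload = {
        "bait_id": domain_set.bait_id,
        "condition": domain_set.condition,
        "parameters": domain_set.params,
        "achieved_fdr": domain_set.achieved_fdr,
        "n_domains": len(domain_set.domains),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------
# genes / chip / chrom sizes
# ---------------------------------------------------------------------


def write_genes_tsv(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_genes_tsv(path: str | Path) -> pd.DataFrame:
    from .spatial_integration import add_tss

    genes = pd.read_csv(path, sep="\t")
    return genes if "tss" in genes.columns else add_tss(genes)


def write_chip_track(track: BinnedChipTrack, ip_path, input_path) -> None:
    bins = track.bins
    ip = bins.assign(value=track.ip)
    inp = bins.assign(value=track.input_)
    write_bedgraph(ip, ip_path)
    write_bedgraph(inp, input_path)


def read_chip_track(
    ip_path, input_path, timepoint: str
) -> BinnedChipTrack:
    ip = read_bedgraph(ip_path)
    inp = read_bedgraph(input_path)
    if not (
        (ip["chrom"] == inp["chrom"]).all()
        and (ip["start"] == inp["start"]).all()
        and (ip["end"] == inp["end"]).all()
    ):
        raise ValueError("IP and input bedGraphs must share the bin grid")
    return BinnedChipTrack(
        bins=ip[["chrom", "start", "end"]].copy(),
        ip=ip["value"].to_numpy(dtype=np.int64),
        input_=inp["value"].to_numpy(dtype=np.int64),
        timepoint=timepoint,
    )


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                out[chrom] = int(size)
    return out


def sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
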