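"""Restriction-fragment coordinate grid.

An in-silico complete digest of a genome with a restriction motif
(HindIII, ``AAGCTT``, by default) yields per-chromosome fragment tilings
and the ordered cut-site positions on which all per-site contact
statistics are computed.  Coordinates are 0-based half-open throughout;
the BED dialect is used on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

HINDIII_MOTIF = "AAGCTT"

_VALID_ALPHABET = set("ACGTN")


class FragmentMapError(ValueError):
    """Raised when fragment coordinates violate the tiling invariants."""


@dataclass(frozen=True)
class FragmentMap:
    """Ordered HindIII-delimited fragments and cut sites per chromosome.

    Parameters
    ----------
    chrom_lengths
        Mapping of chromosome name to length in bp; iteration order fixes
        the global ordering of chromosomes (and hence of sites).
    fragments
        Per chromosome, an ``(n, 2)`` int array of half-open fragment
        coordinates tiling ``[0, length)`` exactly.
    site_positions
        Per chromosome, the ordered interior cut positions; always one
        fewer than the number of fragments.
    """

    chrom_lengths: dict[str, int]
    fragments: dict[str, np.ndarray]
    site_positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------

    def validate(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            frags = self.fragments[chrom]
            sites = self.site_positions[chrom]
            if frags.ndim != 2 or frags.shape[1] != 2:
                raise FragmentMapError(f"{chrom}: fragments must be (n, 2)")
            if frags[0, 0] != 0 or frags[-1, 1] != length:
                raise FragmentMapError(
                    f"{chrom}: fragments do not span [0, {length})"
                )
            if np.any(frags[:, 0] >= frags[:, 1]):
                raise FragmentMapError(f"{chrom}: empty or inverted fragment")
            if np.any(frags[1:, 0] != frags[:-1, 1]):
                raise FragmentMapError(f"{chrom}: fragments do not tile exactly")
            if len(sites) != len(frags) - 1:
                raise FragmentMapError(
                    f"{chrom}: {len(sites)} sites for {len(frags)} fragments"
                )
            if np.any(sites != frags[:-1, 1]):
                raise FragmentMapError(
                    f"{chrom}: site positions disagree with fragment boundaries"
                )

    # -- views --------------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def n_sites(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.site_positions[chrom])
        return sum(len(s) for s in self.site_positions.values())

    def site_chroms(self) -> np.ndarray:
        """Chromosome label of every site, in global site order."""
        parts = [
            np.full(len(self.site_positions[c]), c, dtype=object)
            for c in self.chroms
        ]
        return np.concatenate(parts) if parts else np.array([], dtype=object)

    def all_site_positions(self) -> np.ndarray:
        parts = [self.site_positions[c] for c in self.chroms]
        return (
            np.concatenate(parts) if parts else np.array([], dtype=np.int64)
        )

    def site_slice(self, chrom: str) -> slice:
        """Slice of the global site order occupied by ``chrom``."""
        start = 0
        for c in self.chroms:
            n = len(self.site_positions[c])
            if c == chrom:
                return slice(start, start + n)
            start += n
        raise KeyError(chrom)

    def iter_fragments(self) -> Iterator[tuple[str, int, int]]:
        for chrom in self.chroms:
            for start, end in self.fragments[chrom]:
                yield chrom, int(start), int(end)


# ---------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------


def find_motif_positions(sequence: str, motif: str) -> np.ndarray:
    """Start positions of exact motif matches on the forward strand.

    Overlapping occurrences are reported.  The motif is matched
    literally, so occurrences overlapping ``N`` runs never match.
    """
    seq = sequence.upper()
    hits = []
    i = seq.find(motif)
    while i != -1:
        hits.append(i)
        i = seq.find(motif, i + 1)
    return np.asarray(hits, dtype=np.int64)


def digest_genome(
    sequences: Mapping[str, str], motif: str = HINDIII_MOTIF
) -> FragmentMap:
    """Complete in-silico digest of ``sequences`` with ``motif``.

    Cut positions are reported at the motif start; fragments partition
    each chromosome.  A chromosome without any motif occurrence yields a
    single fragment and zero sites.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if set(motif.upper()) - set("ACGT"):
        raise ValueError(f"motif {motif!r} must be over ACGT")

    chrom_lengths: dict[str, int] = {}
    fragments: dict[str, np.ndarray] = {}
    site_positions: dict[str, np.ndarray] = {}
    for chrom, seq in sequences.items():
        if not seq:
            raise ValueError(f"chromosome {chrom!r} has empty sequence")
        extra = set(seq.upper()) - _VALID_ALPHABET
        if extra:
            raise ValueError(
                f"chromosome {chrom!r} contains invalid characters {extra}"
            )
        length = len(seq)
        cuts = find_motif_positions(seq, motif.upper())
        # interior cuts only: a cut at 0 would create an empty fragment
        cuts = cuts[(cuts > 0) & (cuts < length)]
        bounds = np.concatenate(([0], cuts, [length]))
        chrom_lengths[chrom] = length
        fragments[chrom] = np.column_stack((bounds[:-1], bounds[1:]))
        site_positions[chrom] = cuts
    return FragmentMap(chrom_lengths, fragments, site_positions)


# ---------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------


def write_fragment_map(fragmap: FragmentMap, path: str | Path) -> None:
    """Write fragments as sorted BED3."""
    with open(path, "w") as fh:
        for chrom, start, end in fragmap.iter_fragments():
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_sites_bed(fragmap: FragmentMap, path: str | Path) -> None:
    """Write cut sites as zero-length BED features."""
    with open(path, "w") as fh:
        for chrom in fragmap.chroms:
            for pos in fragmap.site_positions[chrom]:
                fh.write(f"{chrom}\t{pos}\t{pos}\n")


def load_fragment_map(path: str | Path) -> FragmentMap:
    """Load a fragment BED3 file, validating the tiling invariants.

    Violations are reported with the 1-based line numbers of the
    offending records.
    """
    rows: list[tuple[str, int, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FragmentMapError(
                    f"{path}:{lineno}: expected at least 3 BED columns"
                )
            rows.append((parts[0], int(parts[1]), int(parts[2]), lineno))
    if not rows:
        raise FragmentMapError(f"{path}: no fragments found")

    chrom_lengths: dict[str, int] = {}
    fragments: dict[str, np.ndarray] = {}
    site_positions: dict[str, np.ndarray] = {}
    # group rows by chromosome, preserving file order
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, start, end, lineno in rows:
        by_chrom.setdefault(chrom, []).append((start, end, lineno))

    for chrom, recs in by_chrom.items():
        prev_end = None
        prev_line = None
        for start, end, lineno in recs:
            if start >= end:
                raise FragmentMapError(
                    f"{path}:{lineno}: empty or inverted fragment"
                )
            if prev_end is not None:
                if start < prev_end:
                    raise FragmentMapError(
                        f"{path}: lines {prev_line} and {lineno} "
                        f"({chrom}): overlapping or unsorted fragments"
                    )
                if start > prev_end:
                    raise FragmentMapError(
                        f"{path}: lines {prev_line} and {lineno} "
                        f"({chrom}): gap of {start - prev_end} bp "
                        "between consecutive fragments"
                    )
            prev_end, prev_line = end, lineno
        arr = np.asarray([(s, e) for s, e, _ in recs], dtype=np.int64)
        if arr[0, 0] != 0:
            raise FragmentMapError(
                f"{path}: line {recs[0][2]} ({chrom}): first fragment "
                f"starts at {arr[0, 0]}, expected 0"
            )
        chrom_lengths[chrom] = int(arr[-1, 1])
        fragments[chrom] = arr
        site_positions[chrom] = arr[:-1, 1].copy()
    return FragmentMap(chrom_lengths, fragments, site_positions)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-record, line-wrapped) FASTA file into memory."""
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
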