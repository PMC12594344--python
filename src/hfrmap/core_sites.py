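"""Core-genome polymorphic sites from a two-genome alignment.

The ancestry analysis rests on the catalogue of core-genome positions at
which donor and recipient carry different bases. For real data the
catalogue comes from a core-genome aligner's XMFA output, filtered to
syntenic blocks: blocks shorter than 110 bp are discarded (spurious
homologies in accessory genes), as are blocks jumping more than 100 kb in
donor coordinates from the previous retained block, or lying on the
minority strand (synteny breaks). For synthetic pairs the known truth
alignment is used directly via :func:`blocks_from_pair`.

This module also quantifies the density of recombination-initiation
opportunities: maximal runs of strict donor/recipient identity of at
least k bases (k = 20 and 27 bracket the minimal efficient substrate for
RecA-mediated strand exchange), counted per 100-kb bin.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import GenomePair

logger = logging.getLogger(__name__)

__all__ = [
    "SyntenyBlock",
    "read_xmfa",
    "blocks_from_pair",
    "filter_synteny_blocks",
    "extract_polymorphic_sites",
    "homology_opportunity_density",
    "write_sites",
    "read_sites",
]

_GAP = ord("-")
_ACGT = frozenset(b"ACGT")


@dataclass
class SyntenyBlock:
    """One aligned homologous block between recipient and donor.

    Aligned rows are stored in recipient-forward orientation; ``strand``
    is the relative orientation of the donor ('-' means the donor row is
    the reverse complement of donor-forward sequence, and donor
    coordinates descend along the row).
    """

    recipient_interval: tuple[int, int]
    donor_interval: tuple[int, int]
    strand: str
    recipient_aln: str
    donor_aln: str

    @property
    def recipient_length(self) -> int:
        return self.recipient_interval[1] - self.recipient_interval[0]


def read_xmfa(path) -> list[SyntenyBlock]:
    """Parse a two-genome XMFA alignment (parsnp/Mauve style) into blocks.

    The first sequence of each block is taken as the recipient
    (reference). Blocks containing only one genome are skipped with a
    warning. Blocks are returned sorted by recipient start.
    """
    from Bio import AlignIO
    from Bio.Seq import Seq

    blocks: list[SyntenyBlock] = []
    for aln in AlignIO.parse(str(path), "mauve"):
        if len(aln) < 2:
            logger.warning("XMFA block with a single genome skipped")
            continue
        if len(aln) > 2:
            raise ValueError("XMFA block with more than two genomes; expected a pairwise alignment")
        rec, don = aln[0], aln[1]
        r_seq, d_seq = str(rec.seq).upper(), str(don.seq).upper()
        r_strand = rec.annotations.get("strand", 1)
        d_strand = don.annotations.get("strand", 1)
        if r_strand == -1:  # normalise to recipient-forward
            r_seq = str(Seq(r_seq).reverse_complement())
            d_seq = str(Seq(d_seq).reverse_complement())
            d_strand = -d_strand
        blocks.append(
            SyntenyBlock(
                recipient_interval=(rec.annotations["start"], rec.annotations["end"]),
                donor_interval=(don.annotations["start"], don.annotations["end"]),
                strand="+" if d_strand == 1 else "-",
                recipient_aln=r_seq,
                donor_aln=d_seq,
            )
        )
    blocks.sort(key=lambda b: b.recipient_interval[0])
    return blocks


def blocks_from_pair(pair: GenomePair) -> list[SyntenyBlock]:
    """Gap-free synteny blocks from a synthetic pair's truth coordinate map."""
    from . import _seq

    blocks = []
    for rs, ds, ln in pair.coordinate_map.itertuples(index=False):
        blocks.append(
            SyntenyBlock(
                recipient_interval=(int(rs), int(rs + ln)),
                donor_interval=(int(ds), int(ds + ln)),
                strand="+",
                recipient_aln=_seq.decode(pair.recipient_codes[rs : rs + ln]),
                donor_aln=_seq.decode(pair.donor_codes[ds : ds + ln]),
            )
        )
    return blocks


def filter_synteny_blocks(
    blocks: list[SyntenyBlock],
    min_length: int = 110,
    max_jump: int = 100_000,
    order: tuple[str, ...] = ("length", "strand", "distance"),
) -> list[SyntenyBlock]:
    """Retain syntenic blocks per the published rules.

    * ``length``: recipient-side length >= ``min_length`` (110 bp —
      "shorter than" reads strictly less).
    * ``strand``: majority relative orientation (absolute strand is
      alignment-arbitrary, so "opposite strand" means the minority).
    * ``distance``: donor-coordinate gap from the previous retained block
      <= ``max_jump`` (100 kb); measured on the donor side because
      recipient-side gaps are ordinary accessory regions. Blocks are
      walked in recipient order; the first retained block anchors the
      chain. Idempotent.
    """
    out = list(blocks)
    for step in order:
        if step == "length":
            out = [b for b in out if b.recipient_length >= min_length]
        elif step == "strand":
            if out:
                n_plus = sum(1 for b in out if b.strand == "+")
                majority = "+" if n_plus * 2 >= len(out) else "-"
                out = [b for b in out if b.strand == majority]
        elif step == "distance":
            kept: list[SyntenyBlock] = []
            for b in out:
                if kept:
                    prev = kept[-1]
                    gap = max(
                        prev.donor_interval[0] - b.donor_interval[1],
                        b.donor_interval[0] - prev.donor_interval[1],
                        0,
                    )
                    if gap > max_jump:
                        continue
                kept.append(b)
            out = kept
        else:
            raise ValueError(f"unknown filter step {step!r}")
    return out


def _column_coordinates(block: SyntenyBlock):
    """Per-column recipient/donor coordinates and char codes (gap-aware)."""
    r = np.frombuffer(block.recipient_aln.encode(), dtype=np.uint8)
    d = np.frombuffer(block.donor_aln.encode(), dtype=np.uint8)
    r_gap = r == _GAP
    d_gap = d == _GAP
    r_pos = block.recipient_interval[0] + np.cumsum(~r_gap) - 1
    if block.strand == "+":
        d_pos = block.donor_interval[0] + np.cumsum(~d_gap) - 1
    else:
        d_pos = block.donor_interval[1] - np.cumsum(~d_gap)
    return r, d, r_gap, d_gap, r_pos, d_pos


def extract_polymorphic_sites(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    """Substitution sites from filtered blocks.

    One record per aligned column where both characters are unambiguous
    nucleotides and differ. Gap columns and ambiguity codes are skipped.
    Sorted by ``recipient_pos``; duplicates from overlapping blocks keep
    the first occurrence.
    """
    acgt = np.zeros(256, dtype=bool)
    for c in b"ACGT":
        acgt[c] = True
    frames = []
    for b in blocks:
        r, d, r_gap, d_gap, r_pos, d_pos = _column_coordinates(b)
        mask = acgt[r] & acgt[d] & (r != d)
        if not mask.any():
            continue
        frames.append(
            pd.DataFrame(
                {
                    "recipient_pos": r_pos[mask],
                    "donor_pos": d_pos[mask],
                    "recipient_allele": [chr(c) for c in r[mask]],
                    "donor_allele": [chr(c) for c in d[mask]],
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["recipient_pos", "donor_pos", "recipient_allele", "donor_allele"]
        )
    sites = pd.concat(frames, ignore_index=True)
    sites = sites.sort_values("recipient_pos", kind="stable")
    sites = sites.drop_duplicates("recipient_pos", keep="first").reset_index(drop=True)
    return sites


def homology_opportunity_density(
    source,
    ks: tuple[int, ...] = (20, 27),
    bin_size: int = 100_000,
    genome_length: int | None = None,
) -> pd.DataFrame:
    """Per-bin counts of identity runs long enough to seed recombination.

    A run is a maximal stretch of aligned columns where donor and
    recipient are strictly identical unambiguous bases; gaps, ambiguity
    codes, substitutions, and block boundaries all break runs. A run of
    length >= k counts once toward the 100-kb bin of its recipient-side
    midpoint. Returns columns ``bin_start``, ``count_k{k}`` and
    ``per_kb_k{k}`` for each k.
    """
    for k in ks:
        if k <= 0:
            raise ValueError("k must be > 0")
    blocks = blocks_from_pair(source) if isinstance(source, GenomePair) else source
    if genome_length is None:
        genome_length = max((b.recipient_interval[1] for b in blocks), default=0)
    n_bins = max(1, -(-genome_length // bin_size))
    counts = {k: np.zeros(n_bins, dtype=np.int64) for k in ks}
    acgt = np.zeros(256, dtype=bool)
    for c in b"ACGT":
        acgt[c] = True
    for b in blocks:
        r, d, _rg, _dg, r_pos, _d_pos = _column_coordinates(b)
        same = acgt[r] & acgt[d] & (r == d)
        if not same.any():
            continue
        padded = np.concatenate([[False], same, [False]])
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        lengths = ends - starts
        mids = r_pos[(starts + ends - 1) // 2]
        for k in ks:
            sel = lengths >= k
            np.add.at(counts[k], np.clip(mids[sel] // bin_size, 0, n_bins - 1), 1)
    out = pd.DataFrame({"bin_start": np.arange(n_bins) * bin_size})
    for k in ks:
        out[f"count_k{k}"] = counts[k]
        out[f"per_kb_k{k}"] = counts[k] / (bin_size / 1000.0)
    return out


def write_sites(sites: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sites.to_csv(path, sep="\t", index=False)
    return path


def read_sites(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
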