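"""Competitive read classification against donor and recipient genomes.

Each sequenced read is compared against both parental genomes and falls
into one of six categories:

* ``DONOR_BETTER`` / ``RECIPIENT_BETTER`` — matches both genomes but one
  better (the informative reads; they carry strain-specific alleles),
* ``TIE`` — matches both equally well (uninformative),
* ``DONOR_ONLY`` / ``RECIPIENT_ONLY`` — matches a strain-specific
  (accessory) region of one genome,
* ``UNMAPPED`` — placeable on neither.

Two entry points produce the same label table: :func:`classify_from_sam`
consumes alignments from an external mapper (alignment-score comparison),
and :func:`classify_builtin` is an aligner-free classifier for synthetic
data that places reads by exact k-mer seeds and scores them by the
majority vote of the donor/recipient alleles they cover. Both return a
:class:`ClassifiedReads` whose per-read, per-site allele observations
feed the site-frequency and segmentation stages.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _seq
from .synthetic import GenomePair, ReadSet

__all__ = [
    "CATEGORIES",
    "ClassifiedReads",
    "KmerIndex",
    "classify_builtin",
    "classify_from_sam",
    "site_frequencies",
]

CATEGORIES = [
    "DONOR_BETTER",
    "RECIPIENT_BETTER",
    "TIE",
    "DONOR_ONLY",
    "RECIPIENT_ONLY",
    "UNMAPPED",
]

_CAT_DTYPE = pd.CategoricalDtype(CATEGORIES)


def _kmer_codes_1d(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling 2-bit k-mer codes; -1 where the window holds a non-ACGT base."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    c = codes.astype(np.int64)
    out = np.zeros(n, dtype=np.int64)
    for j in range(k):  # Horner scheme, k passes over the array
        out = out * 4 + c[j : j + n]
    bad = np.flatnonzero(codes >= 4)
    if bad.size:
        invalid = np.zeros(codes.size + 1, dtype=np.int64)
        np.add.at(invalid, np.maximum(bad - k + 1, 0), 1)
        np.add.at(invalid, bad + 1, -1)
        out[np.cumsum(invalid)[:n] > 0] = -1
    return out


def _kmer_codes_2d(seqs: np.ndarray) -> np.ndarray:
    """Codes of one k-mer per row (rows are the k columns of a read slice)."""
    m, k = seqs.shape
    c = seqs.astype(np.int64)
    out = np.zeros(m, dtype=np.int64)
    for j in range(k):
        out = out * 4 + c[:, j]
    out[(seqs >= 4).any(axis=1)] = -1
    return out


class KmerIndex:
    """Sorted exact k-mer index of one genome.

    Lookups return the genome position of a k-mer, -1 on a miss, and -1
    for k-mers occurring more than once (ambiguous seeds are unusable).
    """

    def __init__(self, codes: np.ndarray, k: int = 21):
        if k <= 0 or k > 31:
            raise ValueError("k must be in 1..31")
        self.k = k
        kc = _kmer_codes_1d(codes, k)
        valid = np.flatnonzero(kc >= 0)
        order = valid[np.argsort(kc[valid], kind="stable")]
        self._codes = kc[order]
        self._pos = order.astype(np.int64)
        dup = np.zeros(self._codes.size, dtype=bool)
        if self._codes.size > 1:
            same = self._codes[1:] == self._codes[:-1]
            dup[1:] |= same
            dup[:-1] |= same
        self._dup = dup

    def lookup(self, queries: np.ndarray) -> np.ndarray:
        out = np.full(queries.size, -1, dtype=np.int64)
        if self._codes.size == 0:
            return out
        idx = np.searchsorted(self._codes, queries)
        ok = (idx < self._codes.size) & (queries >= 0)
        ok[ok] = self._codes[idx[ok]] == queries[ok]
        ok[ok] &= ~self._dup[idx[ok]]
        out[ok] = self._pos[idx[ok]]
        return out


@dataclass
class ClassifiedReads:
    """Label table plus per-read allele observations at polymorphic sites.

    ``labels`` columns: read_id, recipient_pos (leftmost; -1 when not
    placeable on the recipient), category, score_margin (donor minus
    recipient allele votes), first_site / last_site (positions of the
    first and last covered site supporting the winning allele; -1 if
    none), n_donor, n_recipient.

    ``observations`` columns: read_index (row of ``labels``), site_index
    (row of ``sites``), obs (1 donor allele, 0 recipient allele, -1
    neither, i.e. a sequencing error).
    """

    labels: pd.DataFrame
    observations: pd.DataFrame
    sites: pd.DataFrame
    genome_length: int
    read_length: int

    def category_counts(self) -> pd.Series:
        return self.labels["category"].value_counts().reindex(CATEGORIES, fill_value=0)

    def write_labels(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.labels.to_csv(path, sep="\t", index=False)
        return path


def _interval_mask(pos: np.ndarray, length: int, intervals) -> np.ndarray:
    """True where [pos, pos+length) lies fully inside one of the intervals."""
    out = np.zeros(pos.size, dtype=bool)
    for s, e in intervals:
        out |= (pos >= s) & (pos + length <= e)
    return out


def classify_builtin(
    reads: ReadSet,
    pair: GenomePair,
    sites: pd.DataFrame | None = None,
    k: int = 21,
    seed_step: int = 25,
) -> ClassifiedReads:
    """Aligner-free competitive classification of simulated reads.

    Reads are placed by exact k-mer seeds tried at successive offsets,
    first against the recipient, then against the donor (donor hits are
    projected onto the recipient through the core coordinate map; hits in
    donor-specific sequence become ``DONOR_ONLY``). Placed reads are
    scored by the majority vote of the donor/recipient alleles they carry
    at covered polymorphic sites; ties and site-free reads are ``TIE``
    (site-free reads fully inside recipient-specific sequence are
    ``RECIPIENT_ONLY``).
    """
    if sites is None:
        sites = pair.truth_sites
    n = reads.n_reads
    rl = reads.read_length
    labels_cols = {
        "read_id": reads.names,
        "recipient_pos": np.full(n, -1, dtype=np.int64),
        "category": np.full(n, "UNMAPPED", dtype=object),
        "score_margin": np.zeros(n, dtype=np.int64),
        "first_site": np.full(n, -1, dtype=np.int64),
        "last_site": np.full(n, -1, dtype=np.int64),
        "n_donor": np.zeros(n, dtype=np.int64),
        "n_recipient": np.zeros(n, dtype=np.int64),
    }
    if n == 0:
        labels = pd.DataFrame(labels_cols)
        labels["category"] = labels["category"].astype(_CAT_DTYPE)
        obs = pd.DataFrame({"read_index": [], "site_index": [], "obs": []}).astype(np.int64)
        return ClassifiedReads(labels, obs, sites, pair.genome_length, rl)

    recip_idx = KmerIndex(pair.recipient_codes, k)
    donor_idx = KmerIndex(pair.donor_codes, k)

    pos = np.full(n, -1, dtype=np.int64)  # recipient-frame read start
    donor_only = np.zeros(n, dtype=bool)
    unplaced = np.arange(n)
    offsets = list(range(0, rl - k + 1, max(1, seed_step)))
    if offsets and offsets[-1] != rl - k:
        offsets.append(rl - k)

    dstarts = pair.coordinate_map["donor_start"].to_numpy()
    rstarts = pair.coordinate_map["recipient_start"].to_numpy()
    blens = pair.coordinate_map["length"].to_numpy()

    for off in offsets:
        if unplaced.size == 0:
            break
        q = _kmer_codes_2d(reads.seqs[unplaced, off : off + k])
        # recipient first
        g = recip_idx.lookup(q)
        start = g - off
        hit = (g >= 0) & (start >= 0) & (start + rl <= pair.genome_length)
        pos[unplaced[hit]] = start[hit]
        rest = unplaced[~hit]
        if rest.size:
            qd = q[~hit]
            gd = donor_idx.lookup(qd)
            dstart = gd - off
            ok = (gd >= 0) & (dstart >= 0) & (dstart + rl <= pair.donor_codes.size)
            if ok.any():
                # project donor placement onto the recipient through the core map
                ds = dstart[ok]
                bi = np.clip(np.searchsorted(dstarts, ds, side="right") - 1, 0, dstarts.size - 1)
                infull = (ds >= dstarts[bi]) & (ds + rl <= dstarts[bi] + blens[bi])
                mapped = np.where(infull, rstarts[bi] + (ds - dstarts[bi]), -1)
                tgt = rest[ok]
                pos[tgt[infull]] = mapped[infull]
                donor_only[tgt[~infull]] = True
        unplaced = unplaced[(pos[unplaced] < 0) & ~donor_only[unplaced]]

    placed = np.flatnonzero(pos >= 0)
    ppos = pos[placed]

    # allele votes at covered polymorphic sites
    spos = sites["recipient_pos"].to_numpy(dtype=np.int64)
    d_all = _seq.encode("".join(sites["donor_allele"])) if len(sites) else np.empty(0, np.uint8)
    r_all = _seq.encode("".join(sites["recipient_allele"])) if len(sites) else np.empty(0, np.uint8)
    if placed.size and spos.size:
        i0 = np.searchsorted(spos, ppos)
        i1 = np.searchsorted(spos, ppos + rl)
        counts = i1 - i0
        total = int(counts.sum())
        rr = np.repeat(np.arange(placed.size), counts)
        within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        si = np.repeat(i0, counts) + within
        base = reads.seqs[placed[rr], spos[si] - ppos[rr]]
        is_d = base == d_all[si]
        is_r = base == r_all[si]
        n_d = np.bincount(rr, weights=is_d, minlength=placed.size).astype(np.int64)
        n_r = np.bincount(rr, weights=is_r, minlength=placed.size).astype(np.int64)
        # first site supporting the read's winning allele: the position at
        # which the read's vote is evidence, keeping segment boundaries at
        # site resolution rather than read-start resolution
        big = np.iinfo(np.int64).max
        first_d = np.full(placed.size, big, dtype=np.int64)
        first_r = np.full(placed.size, big, dtype=np.int64)
        np.minimum.at(first_d, rr[is_d], spos[si[is_d]])
        np.minimum.at(first_r, rr[is_r], spos[si[is_r]])
        first = np.where(
            n_d > n_r, first_d, np.where(n_r > n_d, first_r, np.minimum(first_d, first_r))
        )
        first[first == big] = -1
        last_d = np.full(placed.size, -1, dtype=np.int64)
        last_r = np.full(placed.size, -1, dtype=np.int64)
        np.maximum.at(last_d, rr[is_d], spos[si[is_d]])
        np.maximum.at(last_r, rr[is_r], spos[si[is_r]])
        last = np.where(
            n_d > n_r, last_d, np.where(n_r > n_d, last_r, np.maximum(last_d, last_r))
        )
        obs_val = np.where(is_d, 1, np.where(is_r, 0, -1)).astype(np.int64)
        obs = pd.DataFrame(
            {"read_index": placed[rr], "site_index": si.astype(np.int64), "obs": obs_val}
        )
    else:
        n_d = np.zeros(placed.size, dtype=np.int64)
        n_r = np.zeros(placed.size, dtype=np.int64)
        first = np.full(placed.size, -1, dtype=np.int64)
        last = np.full(placed.size, -1, dtype=np.int64)
        obs = pd.DataFrame(
            {
                "read_index": np.empty(0, np.int64),
                "site_index": np.empty(0, np.int64),
                "obs": np.empty(0, np.int64),
            }
        )

    margin = n_d - n_r
    cat = np.where(margin > 0, "DONOR_BETTER", np.where(margin < 0, "RECIPIENT_BETTER", "TIE"))
    no_sites = (n_d + n_r) == 0
    if pair.recipient_accessory and no_sites.any():
        in_acc = _interval_mask(ppos, rl, pair.recipient_accessory)
        cat = np.where(no_sites & in_acc, "RECIPIENT_ONLY", cat)

    labels_cols["recipient_pos"][placed] = ppos
    labels_cols["category"][placed] = cat
    labels_cols["category"][donor_only] = "DONOR_ONLY"
    labels_cols["score_margin"][placed] = margin
    labels_cols["first_site"][placed] = first
    labels_cols["last_site"][placed] = last
    labels_cols["n_donor"][placed] = n_d
    labels_cols["n_recipient"][placed] = n_r
    labels = pd.DataFrame(labels_cols)
    labels["category"] = labels["category"].astype(_CAT_DTYPE)
    return ClassifiedReads(labels, obs, sites, pair.genome_length, rl)


def _best_scores(path: str, mapq_floor: int, split_prefix: bool):
    """Best alignment score per (read, genome) from one SAM/BAM file."""
    import pysam

    best: dict[str, dict[str, tuple[int, int]]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                best.setdefault(aln.query_name, {})
                continue
            if aln.mapping_quality < mapq_floor:
                continue
            if not aln.has_tag("AS"):
                raise ValueError(
                    "alignment record lacks the AS (alignment score) tag required "
                    "for competitive classification"
                )
            ref = fh.get_reference_name(aln.reference_id)
            if split_prefix:
                genome, _, _rest = ref.partition("|")
            else:
                genome = ref
            score = int(aln.get_tag("AS"))
            slot = best.setdefault(aln.query_name, {})
            cur = slot.get(genome)
            if cur is None or score > cur[0]:
                slot[genome] = (score, int(aln.reference_start))
    return best


def classify_from_sam(
    sam_path=None,
    donor_sam=None,
    recipient_sam=None,
    mapq_floor: int = 0,
    coordinate_map: pd.DataFrame | None = None,
    donor_prefix: str = "donor",
    recipient_prefix: str = "recipient",
) -> pd.DataFrame:
    """Classify reads from competitive alignments.

    Accepts either one SAM/BAM against a two-genome reference whose
    reference names are prefixed ``donor|`` / ``recipient|`` (``sam_path``),
    or two files of the same reads mapped to each genome separately
    (``donor_sam`` + ``recipient_sam``). The best alignment score (AS tag)
    per genome decides the category; equal scores are a TIE and
    single-genome hits are DONOR_ONLY / RECIPIENT_ONLY. ``recipient_pos``
    comes from the recipient-side alignment, or is projected through
    ``coordinate_map`` (a GenomePair coordinate map) for donor-only
    placements; alignments under ``mapq_floor`` are ignored and reads with
    no usable alignment are UNMAPPED.

    Returns a label DataFrame with the same columns as
    :attr:`ClassifiedReads.labels` (allele votes are not available from
    scores alone, so n_donor/n_recipient are 0 and score_margin is the
    alignment-score difference).
    """
    if sam_path is not None:
        best = _best_scores(sam_path, mapq_floor, split_prefix=True)
    elif donor_sam is not None and recipient_sam is not None:
        bd = _best_scores(donor_sam, mapq_floor, split_prefix=False)
        br = _best_scores(recipient_sam, mapq_floor, split_prefix=False)
        best = {}
        for name, slot in bd.items():
            if slot:
                (g, sc) = next(iter(slot.items()))
                best.setdefault(name, {})[donor_prefix] = sc
            else:
                best.setdefault(name, {})
        for name, slot in br.items():
            if slot:
                (g, sc) = next(iter(slot.items()))
                best.setdefault(name, {})[recipient_prefix] = sc
            else:
                best.setdefault(name, {})
    else:
        raise ValueError("provide sam_path or both donor_sam and recipient_sam")

    rows = []
    for name, slot in best.items():
        d = slot.get(donor_prefix)
        r = slot.get(recipient_prefix)
        pos, margin, first, last = -1, 0, -1, -1
        if d is None and r is None:
            cat = "UNMAPPED"
        elif d is None:
            cat, pos = "RECIPIENT_ONLY", r[1]
        elif r is None:
            cat = "DONOR_ONLY"
            if coordinate_map is not None:
                ds = coordinate_map["donor_start"].to_numpy()
                rs = coordinate_map["recipient_start"].to_numpy()
                ln = coordinate_map["length"].to_numpy()
                bi = int(np.clip(np.searchsorted(ds, d[1], side="right") - 1, 0, ds.size - 1))
                if ds[bi] <= d[1] < ds[bi] + ln[bi]:
                    pos = int(rs[bi] + d[1] - ds[bi])
        else:
            margin = d[0] - r[0]
            pos = r[1]
            cat = "DONOR_BETTER" if margin > 0 else ("RECIPIENT_BETTER" if margin < 0 else "TIE")
        rows.append((name, pos, cat, margin, first, last, 0, 0))
    labels = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "recipient_pos",
            "category",
            "score_margin",
            "first_site",
            "last_site",
            "n_donor",
            "n_recipient",
        ],
    )
    labels["category"] = labels["category"].astype(_CAT_DTYPE)
    return labels


def site_frequencies(
    classified: ClassifiedReads,
    read_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Donor-allele frequency at each polymorphic site.

    Counts reads carrying the donor vs the recipient allele per site;
    bases matching neither (sequencing errors) are excluded from both
    counts. ``donor_frequency`` is NaN at uncovered sites (flagged by
    ``covered``). ``read_mask`` restricts to a boolean subset of reads
    (used by coverage downsampling).
    """
    obs = classified.observations
    if read_mask is not None:
        obs = obs[read_mask[obs["read_index"].to_numpy()]]
    n_sites = len(classified.sites)
    si = obs["site_index"].to_numpy()
    ov = obs["obs"].to_numpy()
    donor = np.bincount(si[ov == 1], minlength=n_sites)
    recip = np.bincount(si[ov == 0], minlength=n_sites)
    tot = donor + recip
    with np.errstate(invalid="ignore"):
        freq = np.where(tot > 0, donor / np.maximum(tot, 1), np.nan)
    return pd.DataFrame(
        {
            "recipient_pos": classified.sites["recipient_pos"].to_numpy(),
            "donor_count": donor,
            "recipient_count": recip,
            "donor_frequency": freq,
            "covered": tot > 0,
        }
    )
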