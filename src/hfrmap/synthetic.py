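"""Synthetic conjugation crosses with machine-readable truth.

This module generates everything the analysis consumes, with known ground
truth: a donor/recipient genome pair (divergent core plus optional
strain-specific accessory segments), recombinant clones carrying donor
tracts (one forced to cover the selected marker), sequencing reads with
substitution errors, and pooled libraries of many selected recombinants.

Model conventions
-----------------
* Coordinates are 0-based, half-open; the recipient genome is the
  reference frame.
* Genomes are linear; fragments never wrap the origin.
* Core divergence is substitution-only (no indels between cores), so a
  recombinant has exactly the recipient's length and coordinate frame.
* Reads are single-end, fixed length, uniform start positions,
  i.i.d. substitution errors, constant Phred quality.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _seq
from .distributions import FragmentLengthDistribution

__all__ = [
    "GenomePairConfig",
    "GenomePair",
    "RecombinantTruth",
    "Recombinant",
    "ReadSet",
    "generate_genome_pair",
    "simulate_recombinant",
    "simulate_reads",
    "build_pool",
    "read_fastq",
]


# ---------------------------------------------------------------------------
# genome pair
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomePairConfig:
    """Parameters of a donor/recipient pair.

    ``genome_length`` is the shared (core) length in bases; ``divergence``
    the per-site substitution probability between the cores;
    ``accessory_segments`` a list of ``(genome, length, count)`` with
    genome in {"donor", "recipient"} describing strain-specific insertions.
    """

    genome_length: int
    divergence: float
    accessory_segments: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be > 0")
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError("divergence must be in [0, 1)")
        for genome, length, count in self.accessory_segments:
            if genome not in ("donor", "recipient"):
                raise ValueError(f"accessory genome must be donor/recipient, got {genome!r}")
            if length <= 0 or count <= 0:
                raise ValueError("accessory segment lengths and counts must be > 0")


@dataclass
class GenomePair:
    """A donor/recipient pair with its truth alignment.

    ``coordinate_map`` lists maximal core blocks as a DataFrame with columns
    ``recipient_start``, ``donor_start``, ``length`` (monotone in both
    genomes). ``truth_sites`` has columns ``recipient_pos``, ``donor_pos``,
    ``recipient_allele``, ``donor_allele``.
    """

    donor_codes: np.ndarray
    recipient_codes: np.ndarray
    coordinate_map: pd.DataFrame
    truth_sites: pd.DataFrame
    donor_accessory: list = field(default_factory=list)
    recipient_accessory: list = field(default_factory=list)
    core_length: int = 0

    @property
    def donor_sequence(self) -> str:
        return _seq.decode(self.donor_codes)

    @property
    def recipient_sequence(self) -> str:
        return _seq.decode(self.recipient_codes)

    @property
    def genome_length(self) -> int:
        """Recipient genome length (the analysis frame)."""
        return int(self.recipient_codes.size)

    def donor_to_recipient(self, pos: np.ndarray) -> np.ndarray:
        """Map donor coordinates to recipient coordinates (-1 if accessory)."""
        pos = np.asarray(pos, dtype=np.int64)
        ds = self.coordinate_map["donor_start"].to_numpy()
        rs = self.coordinate_map["recipient_start"].to_numpy()
        ln = self.coordinate_map["length"].to_numpy()
        idx = np.searchsorted(ds, pos, side="right") - 1
        idx = np.clip(idx, 0, ds.size - 1)
        off = pos - ds[idx]
        ok = (off >= 0) & (off < ln[idx])
        out = np.where(ok, rs[idx] + off, -1)
        return out

    def recipient_is_core(self, pos: int) -> bool:
        for s, e in self.recipient_accessory:
            if s <= pos < e:
                return False
        return 0 <= pos < self.genome_length

    def swapped(self) -> "GenomePair":
        """The same pair with donor and recipient roles exchanged."""
        cmap = self.coordinate_map.rename(
            columns={"recipient_start": "donor_start", "donor_start": "recipient_start"}
        )[["recipient_start", "donor_start", "length"]]
        sites = self.truth_sites.rename(
            columns={
                "recipient_pos": "donor_pos",
                "donor_pos": "recipient_pos",
                "recipient_allele": "donor_allele",
                "donor_allele": "recipient_allele",
            }
        )[["recipient_pos", "donor_pos", "recipient_allele", "donor_allele"]]
        return GenomePair(
            donor_codes=self.recipient_codes,
            recipient_codes=self.donor_codes,
            coordinate_map=cmap,
            truth_sites=sites.sort_values("recipient_pos", ignore_index=True),
            donor_accessory=list(self.recipient_accessory),
            recipient_accessory=list(self.donor_accessory),
            core_length=self.core_length,
        )

    # -- IO ---------------------------------------------------------------
    def write_fasta(self, outdir) -> tuple[Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, codes in (("donor", self.donor_codes), ("recipient", self.recipient_codes)):
            p = outdir / f"{name}.fasta"
            seq = _seq.decode(codes)
            with open(p, "w") as fh:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
            paths.append(p)
        return tuple(paths)

    def write_truth_sites(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.truth_sites.to_csv(path, sep="\t", index=False)
        return path


def _insert_segments(core: np.ndarray, insertions: list[tuple[int, np.ndarray]]):
    """Insert segments at core positions; return sequence and accessory intervals."""
    insertions = sorted(insertions, key=lambda t: t[0])
    parts, acc = [], []
    prev = 0
    shift = 0
    for pos, seg in insertions:
        parts.append(core[prev:pos])
        acc.append((pos + shift, pos + shift + seg.size))
        parts.append(seg)
        shift += seg.size
        prev = pos
    parts.append(core[prev:])
    return np.concatenate(parts) if parts else core, acc


def _core_shift(core_pos: np.ndarray, insertions: list[tuple[int, np.ndarray]]) -> np.ndarray:
    """Offset added to core positions by insertions at or before them."""
    if not insertions:
        return np.zeros(core_pos.size, dtype=np.int64)
    ipos = np.array([p for p, _ in insertions], dtype=np.int64)
    ilen = np.array([s.size for _, s in insertions], dtype=np.int64)
    order = np.argsort(ipos, kind="stable")
    ipos, ilen = ipos[order], ilen[order]
    cum = np.concatenate([[0], np.cumsum(ilen)])
    return cum[np.searchsorted(ipos, core_pos, side="right")]


def generate_genome_pair(config: GenomePairConfig, outdir=None) -> GenomePair:
    """Generate a donor/recipient pair from a random ancestor.

    The recipient core equals the ancestor; the donor core differs at
    Bernoulli(divergence) positions (uniform among the 3 alternative
    bases). Accessory segments are random sequence inserted at uniform
    positions of the respective genome and excluded from ``truth_sites``.
    If ``outdir`` is given, FASTA genomes and a truth-site TSV are written
    there.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    ancestor = _seq.random_codes(rng, L)
    sub_pos = np.flatnonzero(rng.random(L) < config.divergence)
    donor_core = _seq.mutate_codes(rng, ancestor, sub_pos)

    ins_d: list[tuple[int, np.ndarray]] = []
    ins_r: list[tuple[int, np.ndarray]] = []
    for genome, length, count in config.accessory_segments:
        for _ in range(int(count)):
            pos = int(rng.integers(0, L + 1))
            seg = _seq.random_codes(rng, int(length))
            (ins_d if genome == "donor" else ins_r).append((pos, seg))
    ins_d.sort(key=lambda t: t[0])
    ins_r.sort(key=lambda t: t[0])

    donor_codes, donor_acc = _insert_segments(donor_core, ins_d)
    recipient_codes, recip_acc = _insert_segments(ancestor, ins_r)

    shift_d = _core_shift(sub_pos, ins_d)
    shift_r = _core_shift(sub_pos, ins_r)
    truth = pd.DataFrame(
        {
            "recipient_pos": sub_pos + shift_r,
            "donor_pos": sub_pos + shift_d,
            "recipient_allele": [_seq.ALPHABET[c] for c in ancestor[sub_pos]],
            "donor_allele": [_seq.ALPHABET[c] for c in donor_core[sub_pos]],
        }
    )

    # core blocks: split at every insertion point of either genome
    cuts = sorted({0, L} | {p for p, _ in ins_d} | {p for p, _ in ins_r})
    starts = np.array(cuts[:-1], dtype=np.int64)
    ends = np.array(cuts[1:], dtype=np.int64)
    keep = ends > starts
    starts, ends = starts[keep], ends[keep]
    cmap = pd.DataFrame(
        {
            "recipient_start": starts + _core_shift(starts, ins_r),
            "donor_start": starts + _core_shift(starts, ins_d),
            "length": ends - starts,
        }
    )

    pair = GenomePair(
        donor_codes=donor_codes,
        recipient_codes=recipient_codes,
        coordinate_map=cmap,
        truth_sites=truth,
        donor_accessory=donor_acc,
        recipient_accessory=recip_acc,
        core_length=L,
    )
    if outdir is not None:
        pair.write_fasta(outdir)
        pair.write_truth_sites(Path(outdir) / "truth_sites.tsv")
    return pair


# ---------------------------------------------------------------------------
# recombinant clones
# ---------------------------------------------------------------------------

@dataclass
class RecombinantTruth:
    """True donor-derived intervals of one clone (recipient frame)."""

    fragments: list  # list of (start, end), merged, sorted
    marker_position: int
    clone_id: str = "clone"

    def marker_fragment(self) -> tuple[int, int]:
        for s, e in self.fragments:
            if s <= self.marker_position < e:
                return (s, e)
        raise ValueError("no fragment contains the marker")

    def write_bed(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            for s, e in self.fragments:
                mark = "marker" if s <= self.marker_position < e else "donor"
                fh.write(f"recipient\t{s}\t{e}\t{mark}\n")
        return path


@dataclass
class Recombinant:
    """Truth plus the recombinant's sequence (recipient frame)."""

    truth: RecombinantTruth
    codes: np.ndarray

    @property
    def sequence(self) -> str:
        return _seq.decode(self.codes)


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _overlaps(a: tuple[int, int], b: tuple[int, int] | None) -> bool:
    return b is not None and a[0] < b[1] and b[0] < a[1]


def simulate_recombinant(
    pair: GenomePair,
    marker_position: int,
    marker_dist: FragmentLengthDistribution,
    extra_count=("poisson", 1.5),
    extra_dist: FragmentLengthDistribution | None = None,
    placement_window: int = 500_000,
    placement: str = "window",
    counter_selected: tuple[int, int] | None = None,
    seed: int = 0,
    clone_id: str = "clone",
) -> Recombinant:
    """Simulate one selected recombinant.

    The marker-covering fragment has length L drawn from ``marker_dist``
    and a left overhang uniform on [0, L). Extra fragments (count fixed if
    ``extra_count`` is an int, else ``("poisson", lam)``) get lengths from
    ``extra_dist`` (defaults to ``marker_dist``) and are placed uniformly
    within ``placement_window`` bases of the marker fragment
    (``placement="window"``) or genome-wide (``placement="genome"``).
    Fragments overlapping ``counter_selected`` (an interval the selection
    forbids donor DNA to replace, e.g. a resistance cassette in the
    recipient) are redrawn. The recombinant sequence is the recipient with
    donor alleles substituted inside the fragments.
    """
    rng = np.random.default_rng(seed)
    glen = pair.genome_length
    if not pair.recipient_is_core(marker_position):
        raise ValueError("marker_position must lie in the core genome")
    if extra_dist is None:
        extra_dist = marker_dist

    def draw_marker_fragment() -> tuple[int, int]:
        for _ in range(1000):
            L = max(1, int(round(float(marker_dist.sample(rng, 1)[0]))))
            u = int(rng.integers(0, L))
            s, e = marker_position - u, marker_position - u + L
            s, e = max(0, s), min(glen, e)
            if not _overlaps((s, e), counter_selected):
                return (s, e)
        raise RuntimeError("could not place marker fragment away from counter-selected site")

    mfrag = draw_marker_fragment()

    if isinstance(extra_count, (int, np.integer)):
        n_extra = int(extra_count)
    else:
        family, param = extra_count
        if family != "poisson":
            raise ValueError(f"unsupported extra_count family {family!r}")
        n_extra = int(rng.poisson(param))

    extras: list[tuple[int, int]] = []
    for _ in range(n_extra):
        for _ in range(1000):
            L = max(1, int(round(float(extra_dist.sample(rng, 1)[0]))))
            if placement == "window":
                lo = max(0, mfrag[0] - placement_window)
                hi = min(glen, mfrag[1] + placement_window)
            elif placement == "genome":
                lo, hi = 0, glen
            else:
                raise ValueError(f"unknown placement {placement!r}")
            if hi - lo <= L:
                s = lo
            else:
                s = int(rng.integers(lo, hi - L))
            e = min(glen, s + L)
            if not _overlaps((s, e), counter_selected):
                extras.append((s, e))
                break
        else:
            raise RuntimeError("could not place extra fragment away from counter-selected site")

    fragments = _merge_intervals([mfrag] + extras)
    truth = RecombinantTruth(fragments=fragments, marker_position=marker_position, clone_id=clone_id)

    codes = pair.recipient_codes.copy()
    site_pos = pair.truth_sites["recipient_pos"].to_numpy()
    donor_alleles = _seq.encode("".join(pair.truth_sites["donor_allele"]))
    for s, e in fragments:
        i0, i1 = np.searchsorted(site_pos, (s, e))
        codes[site_pos[i0:i1]] = donor_alleles[i0:i1]
    return Recombinant(truth=truth, codes=codes)


# ---------------------------------------------------------------------------
# reads and pools
# ---------------------------------------------------------------------------

@dataclass
class ReadSet:
    """Simulated single-end reads as a dense code matrix."""

    names: list
    seqs: np.ndarray  # (n_reads, read_length) uint8
    starts: np.ndarray  # true origin, for validation only

    @property
    def n_reads(self) -> int:
        return int(self.seqs.shape[0])

    @property
    def read_length(self) -> int:
        return int(self.seqs.shape[1])

    def write_fastq(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        qual = "I" * self.read_length
        with open(path, "w") as fh:
            for name, row in zip(self.names, self.seqs):
                fh.write(f"@{name}\n{_seq.decode(row)}\n+\n{qual}\n")
        return path

    @classmethod
    def concat(cls, sets: Sequence["ReadSet"]) -> "ReadSet":
        names: list = []
        for rs in sets:
            names.extend(rs.names)
        return cls(
            names=names,
            seqs=np.concatenate([rs.seqs for rs in sets]) if sets else np.empty((0, 0), np.uint8),
            starts=np.concatenate([rs.starts for rs in sets]) if sets else np.empty(0, np.int64),
        )


def _sample_reads(codes, n_reads, read_length, error_rate, rng, prefix) -> ReadSet:
    glen = codes.size
    starts = rng.integers(0, glen - read_length + 1, size=n_reads)
    idx = starts[:, None] + np.arange(read_length)
    seqs = codes[idx]
    if error_rate > 0:
        err = rng.random(seqs.shape) < error_rate
        shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        seqs = seqs.copy()
        seqs[err] = (seqs[err] + shift) % 4
    names = [f"{prefix}:{i}|pos={int(s)}" for i, s in enumerate(starts)]
    return ReadSet(names=names, seqs=seqs, starts=starts.astype(np.int64))


def simulate_reads(
    source,
    depth: float,
    read_length: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
    prefix: str = "r",
    fastq_path=None,
) -> ReadSet:
    """Draw round(depth * length / read_length) uniform-start reads.

    ``source`` may be a code array, a string, or a :class:`Recombinant`.
    The true origin is encoded in each read name (validation only).
    """
    if isinstance(source, Recombinant):
        codes = source.codes
    elif isinstance(source, str):
        codes = _seq.encode(source)
    else:
        codes = np.asarray(source, dtype=np.uint8)
    if codes.size == 0:
        raise ValueError("empty sequence")
    if read_length > codes.size:
        raise ValueError("read_length exceeds sequence length")
    n_reads = int(round(depth * codes.size / read_length))
    rng = np.random.default_rng(seed)
    rs = _sample_reads(codes, n_reads, read_length, error_rate, rng, prefix)
    if fastq_path is not None:
        rs.write_fastq(fastq_path)
    return rs


def build_pool(
    clones: Sequence[Recombinant],
    weights: Sequence[float],
    total_depth: float,
    read_length: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
    fastq_path=None,
    manifest_path=None,
) -> tuple[ReadSet, dict]:
    """Pool reads from many clones with multinomial per-clone read counts.

    Returns the pooled :class:`ReadSet` and a manifest dict recording the
    per-clone contribution; read names are prefixed with the clone id.
    """
    if len(clones) == 0:
        raise ValueError("need at least one clone")
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(clones),) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be >= 0, one per clone, not all zero")
    glen = clones[0].codes.size
    n_total = int(round(total_depth * glen / read_length))
    counts = np.random.default_rng(seed + 10_000_019).multinomial(n_total, w / w.sum())
    parts = []
    for j, (clone, n) in enumerate(zip(clones, counts)):
        if n == 0:
            continue
        # per-clone stream seeded at seed+j: a single-clone pool is then
        # byte-identical to simulate_reads on that clone at the same seed
        parts.append(
            _sample_reads(
                clone.codes,
                int(n),
                read_length,
                error_rate,
                np.random.default_rng(seed + j),
                prefix=clone.truth.clone_id,
            )
        )
    pool = ReadSet.concat(parts)
    manifest = {
        "total_reads": n_total,
        "read_length": read_length,
        "error_rate": error_rate,
        "clones": [
            {"clone_id": c.truth.clone_id, "weight": float(wi), "reads": int(n)}
            for c, wi, n in zip(clones, w, counts)
        ],
    }
    if fastq_path is not None:
        pool.write_fastq(fastq_path)
    if manifest_path is not None:
        Path(manifest_path).parent.mkdir(parents=True, exist_ok=True)
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)
    return pool, manifest


def read_fastq(path) -> ReadSet:
    """Load a FASTQ file into a :class:`ReadSet` (fixed read length required)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    names, seqs = [], []
    with open(path) as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            names.append(title)
            seqs.append(_seq.encode(seq))
    if not names:
        return ReadSet(names=[], seqs=np.empty((0, 0), np.uint8), starts=np.empty(0, np.int64))
    mat = np.vstack(seqs)
    starts = np.full(len(names), -1, dtype=np.int64)
    for i, t in enumerate(names):
        if "|pos=" in t:
            starts[i] = int(t.rsplit("|pos=", 1)[1].split()[0])
    return ReadSet(names=names, seqs=mat, starts=starts)
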