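"""Donor-tract delineation in individual recombinant genomes.

Two independent methods recover the donor-derived intervals of a clone:

1. **HMM on binary read labels.** Reads ordered by genomic position carry
   a 0/1 label (1 = matched the donor better). A homogeneous 2-state
   hidden Markov chain (states donor / recipient, Bernoulli emissions
   e_d and e_r, symmetric per-observation switch probability t) is
   decoded by Viterbi; maximal donor-state runs become donor fragments.
   Forward–backward posteriors flag clones whose ancestry never resolves.

2. **Changepoint segmentation of donor-allele frequencies.** The
   per-site donor frequency series is partitioned under a
   piecewise-constant-mean model, minimising total within-segment sum of
   squares plus ``penalty`` (default 3) per changepoint, solved exactly
   with PELT. Segments with mean donor frequency > 0.5 become donor
   fragments. This is the higher-resolution method, but more exposed to
   sequencing errors at single sites.

Fragment boundaries are reported at observation coordinates (the
first/last supporting site), half-open, recipient frame, which keeps the
two methods comparable base-for-base.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .classify import ClassifiedReads, site_frequencies

__all__ = [
    "HmmParams",
    "ChangepointParams",
    "Fragment",
    "BinarySeries",
    "hmm_segment",
    "hmm_posterior",
    "flag_unresolved",
    "changepoint_segment",
    "pelt_changepoints",
    "compare_methods",
    "fragment_stats",
    "downsample_robustness",
    "flag_marker",
    "write_fragments_bed",
]


@dataclass(frozen=True)
class HmmParams:
    """2-state Bernoulli HMM parameters.

    e_d / e_r: probability that a read over donor- / recipient-derived
    sequence is labeled 1 (donor-better); t: per-observation switch
    probability; pi_d: initial donor-state probability. Defaults reflect
    that mislabels need a sequencing error to hit the few discriminating
    sites a read covers, and that tracts span thousands of reads.
    """

    e_d: float = 0.95
    e_r: float = 0.05
    t: float = 1e-3
    pi_d: float = 0.5

    def __post_init__(self) -> None:
        for name in ("e_d", "e_r", "t", "pi_d"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.e_d <= self.e_r:
            raise ValueError("e_d must exceed e_r")


@dataclass(frozen=True)
class ChangepointParams:
    penalty: float = 3.0
    min_segment_sites: int = 2

    def __post_init__(self) -> None:
        if self.penalty < 0:
            raise ValueError("penalty must be >= 0")
        if self.min_segment_sites < 1:
            raise ValueError("min_segment_sites must be >= 1")


@dataclass
class Fragment:
    """A contiguous single-origin interval (0-based half-open, recipient frame)."""

    start: int
    end: int
    origin: str = "donor"
    n_obs: int = 0
    contains_marker: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("fragment start must precede end")


@dataclass
class BinarySeries:
    """Position-ordered 0/1 read labels (1 = donor-better).

    ``end_positions`` (half-open) carries each observation's rightmost
    supporting coordinate + 1, so that a fragment's end is reported at its
    last supporting site rather than the boundary read's start.
    """

    positions: np.ndarray
    labels: np.ndarray
    end_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.positions.size != self.labels.size:
            raise ValueError("positions and labels must have equal length")
        if self.end_positions is None:
            self.end_positions = self.positions + 1
        else:
            self.end_positions = np.asarray(self.end_positions, dtype=np.int64)
            if self.end_positions.size != self.positions.size:
                raise ValueError("end_positions must match positions")

    @classmethod
    def from_classified(cls, classified: ClassifiedReads, use: str = "first_site",
                        read_mask: np.ndarray | None = None) -> "BinarySeries":
        """Informative reads only; position is the first covered site
        supporting the read's label (``use="first_site"``) or the read's
        leftmost coordinate (``use="read_start"``). Stable sort keeps
        equal-position reads in input order."""
        lab = classified.labels
        if read_mask is not None:
            lab = lab[read_mask]
        m = lab["category"].isin(["DONOR_BETTER", "RECIPIENT_BETTER"])
        lab = lab[m]
        first = lab["first_site"].to_numpy()
        last = lab["last_site"].to_numpy()
        start = lab["recipient_pos"].to_numpy()
        if use == "first_site":
            pos = np.where(first >= 0, first, start)
            end = np.where(last >= 0, last + 1, pos + 1)
        elif use == "read_start":
            pos = start
            end = start + classified.read_length
        else:
            raise ValueError("use must be 'first_site' or 'read_start'")
        y = (lab["category"] == "DONOR_BETTER").to_numpy().astype(np.int8)
        order = np.argsort(pos, kind="stable")
        return cls(positions=pos[order], labels=y[order], end_positions=end[order])


# ---------------------------------------------------------------------------
# HMM
# ---------------------------------------------------------------------------

def _hmm_log_matrices(params: HmmParams):
    # state 0 = recipient, 1 = donor
    log_e = np.log(
        [[1.0 - params.e_r, params.e_r], [1.0 - params.e_d, params.e_d]]
    )  # [state, label]
    log_t = np.log(
        [[1.0 - params.t, params.t], [params.t, 1.0 - params.t]]
    )
    log_pi = np.log([1.0 - params.pi_d, params.pi_d])
    return log_e, log_t, log_pi


def viterbi_path(labels: np.ndarray, params: HmmParams) -> np.ndarray:
    """Most likely state sequence (0 recipient, 1 donor)."""
    y = np.asarray(labels, dtype=np.int64)
    n = y.size
    if n == 0:
        return np.empty(0, dtype=np.int8)
    log_e, log_t, log_pi = _hmm_log_matrices(params)
    delta = log_pi + log_e[:, y[0]]
    back = np.empty((n, 2), dtype=np.int8)
    for i in range(1, n):
        cand = delta[:, None] + log_t  # [from, to]
        back[i] = np.argmax(cand, axis=0)
        delta = cand[back[i], [0, 1]] + log_e[:, y[i]]
    states = np.empty(n, dtype=np.int8)
    states[-1] = int(np.argmax(delta))
    for i in range(n - 1, 0, -1):
        states[i - 1] = back[i, states[i]]
    return states


def hmm_posterior(labels: np.ndarray, params: HmmParams) -> np.ndarray:
    """Forward–backward posterior probability of the donor state."""
    y = np.asarray(labels, dtype=np.int64)
    n = y.size
    if n == 0:
        return np.empty(0)
    log_e, log_t, log_pi = _hmm_log_matrices(params)
    e = np.exp(log_e)
    T = np.exp(log_t)
    alpha = np.empty((n, 2))
    c = np.empty(n)
    a = np.exp(log_pi) * e[:, y[0]]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for i in range(1, n):
        a = (alpha[i - 1] @ T) * e[:, y[i]]
        c[i] = a.sum()
        alpha[i] = a / c[i]
    beta = np.empty((n, 2))
    beta[-1] = 1.0
    for i in range(n - 2, -1, -1):
        beta[i] = (T @ (e[:, y[i + 1]] * beta[i + 1])) / c[i + 1]
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post[:, 1]


def _runs_to_fragments(
    positions: np.ndarray, states: np.ndarray, end_positions: np.ndarray | None = None
) -> list[Fragment]:
    frags: list[Fragment] = []
    if states.size == 0:
        return frags
    if end_positions is None:
        end_positions = np.asarray(positions, dtype=np.int64) + 1
    padded = np.concatenate([[0], states == 1, [0]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for i0, i1 in zip(starts, ends):
        s = int(positions[i0])
        e = int(end_positions[i0:i1].max())
        frags.append(Fragment(start=s, end=e, origin="donor", n_obs=int(i1 - i0)))
    return frags


def hmm_segment(series: BinarySeries, params: HmmParams = HmmParams()) -> list[Fragment]:
    """Viterbi-decoded donor fragments from a binary label series."""
    states = viterbi_path(series.labels, params)
    return _runs_to_fragments(series.positions, states, series.end_positions)


def flag_unresolved(
    posterior: np.ndarray, min_confidence: float = 0.8, max_fraction: float = 0.2
) -> bool:
    """True when ancestry stays ambiguous: the max-state posterior is below
    ``min_confidence`` over more than ``max_fraction`` of observations
    (seen in clones whose recombination had not resolved in the sequenced
    colony)."""
    if posterior.size == 0:
        return False
    conf = np.maximum(posterior, 1.0 - posterior)
    return float(np.mean(conf < min_confidence)) > max_fraction


# ---------------------------------------------------------------------------
# changepoint
# ---------------------------------------------------------------------------

def pelt_changepoints(values: np.ndarray, penalty: float, min_segment: int = 1) -> list[int]:
    """Exact penalized optimal partitioning (PELT) of a 1-D series.

    Minimises sum of within-segment SSE plus ``penalty`` per changepoint;
    returns interior changepoint indices (a changepoint at i splits
    values[:i] | values[i:]).
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2 * min_segment:
        return []
    cs = np.concatenate([[0.0], np.cumsum(v)])
    css = np.concatenate([[0.0], np.cumsum(v * v)])

    def seg_cost(t: np.ndarray, s: int) -> np.ndarray:
        m = s - t
        return css[s] - css[t] - (cs[s] - cs[t]) ** 2 / m

    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    prev = np.zeros(n + 1, dtype=np.int64)
    cand = np.array([0], dtype=np.int64)
    for s in range(min_segment, n + 1):
        new_t = s - min_segment
        if new_t > 0:
            cand = np.append(cand, new_t)
        costs = F[cand] + seg_cost(cand, s) + penalty
        j = int(np.argmin(costs))
        F[s] = costs[j]
        prev[s] = cand[j]
        # PELT pruning (K = 0 for the SSE cost)
        cand = cand[F[cand] + seg_cost(cand, s) <= F[s]]
    cps = []
    s = n
    while s > 0:
        t = int(prev[s])
        if t > 0:
            cps.append(t)
        s = t
    return sorted(cps)


def changepoint_segment(
    freqs: pd.DataFrame,
    params: ChangepointParams = ChangepointParams(),
    donor_threshold: float = 0.5,
) -> list[Fragment]:
    """Donor fragments from the per-site donor-frequency series.

    Sites without coverage are dropped. The covered series is segmented
    by :func:`pelt_changepoints`; segments whose mean donor frequency
    exceeds ``donor_threshold`` become donor fragments, with adjacent
    donor segments merged. Fewer than 2 usable sites yield at most one
    whole-series segment.
    """
    use = freqs[freqs["donor_frequency"].notna()]
    pos = use["recipient_pos"].to_numpy(dtype=np.int64)
    val = use["donor_frequency"].to_numpy(dtype=float)
    if pos.size == 0:
        return []
    if pos.size < 2:
        cps: list[int] = []
    else:
        cps = pelt_changepoints(val, params.penalty, params.min_segment_sites)
    bounds = [0] + cps + [pos.size]
    is_donor = np.zeros(pos.size, dtype=np.int8)
    for a, b in zip(bounds[:-1], bounds[1:]):
        if val[a:b].mean() > donor_threshold:
            is_donor[a:b] = 1
    return _runs_to_fragments(pos, is_donor)


# ---------------------------------------------------------------------------
# comparison & statistics
# ---------------------------------------------------------------------------

def _merged(frags: list[Fragment]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for f in sorted(frags, key=lambda f: f.start):
        if out and f.start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], f.end))
        else:
            out.append((f.start, f.end))
    return out


def _territory(ivs: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in ivs)


def _intersection(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total, i, j = 0, 0, 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def compare_methods(
    frags_hmm: list[Fragment],
    frags_freq: list[Fragment],
    min_reciprocal_overlap: float = 0.5,
) -> dict:
    """Concordance between the two segmentations of one clone.

    Reports the per-base Jaccard index of donor territory, matched
    fragment pairs (reciprocal overlap >= ``min_reciprocal_overlap`` of
    both lengths), and fragments unique to each method.
    """
    a = _merged(frags_hmm)
    b = _merged(frags_freq)
    inter = _intersection(a, b)
    union = _territory(a) + _territory(b) - inter
    jaccard = 1.0 if union == 0 else inter / union
    matched = []
    used_b: set[int] = set()
    for i, fa in enumerate(frags_hmm):
        for j, fb in enumerate(frags_freq):
            if j in used_b:
                continue
            ov = max(0, min(fa.end, fb.end) - max(fa.start, fb.start))
            if ov >= min_reciprocal_overlap * fa.length and ov >= min_reciprocal_overlap * fb.length:
                matched.append((i, j))
                used_b.add(j)
                break
    matched_a = {i for i, _ in matched}
    return {
        "jaccard": jaccard,
        "matched_pairs": matched,
        "unique_hmm": [i for i in range(len(frags_hmm)) if i not in matched_a],
        "unique_freq": [j for j in range(len(frags_freq)) if j not in used_b],
    }


def flag_marker(fragments: list[Fragment], marker: int) -> list[Fragment]:
    for f in fragments:
        f.contains_marker = f.start <= marker < f.end
    return fragments


def fragment_stats(clones: dict, marker: int | None = None) -> dict:
    """Summary statistics of donor fragments across clones.

    ``clones`` maps clone_id to a fragment list. Returns a dict with a
    per-fragment table, per-clone totals, overall medians/means split by
    marker coverage, and a two-sided rank-sum (Mann–Whitney) comparison
    of marker-containing vs other fragment lengths.
    """
    rows = []
    for cid, frags in clones.items():
        if marker is not None:
            flag_marker(frags, marker)
        for f in frags:
            rows.append((cid, f.start, f.end, f.length, f.contains_marker))
    table = pd.DataFrame(
        rows, columns=["clone_id", "start", "end", "length", "contains_marker"]
    )
    per_clone = (
        table.groupby("clone_id")["length"].agg(n_fragments="count", total_length="sum")
        if len(table)
        else pd.DataFrame(columns=["n_fragments", "total_length"])
    )
    out = {
        "fragments": table,
        "per_clone": per_clone,
        "n_clones": len(clones),
        "median_length": float(table["length"].median()) if len(table) else float("nan"),
        "mean_length": float(table["length"].mean()) if len(table) else float("nan"),
        "mean_fragments_per_clone": float(per_clone["n_fragments"].mean())
        if len(per_clone)
        else float("nan"),
    }
    mk = table[table["contains_marker"]]["length"]
    other = table[~table["contains_marker"]]["length"]
    out["median_length_marker"] = float(mk.median()) if len(mk) else float("nan")
    out["median_length_other"] = float(other.median()) if len(other) else float("nan")
    if len(mk) and len(other):
        res = sstats.mannwhitneyu(mk, other, alternative="two-sided")
        out["ranksum_statistic"] = float(res.statistic)
        out["ranksum_pvalue"] = float(res.pvalue)
    return out


# ---------------------------------------------------------------------------
# coverage robustness
# ---------------------------------------------------------------------------

def downsample_robustness(
    classified: ClassifiedReads,
    fractions=(1.0, 0.5, 0.4, 0.25, 0.175, 0.1),
    seed: int = 0,
    hmm_params: HmmParams = HmmParams(),
    cp_params: ChangepointParams = ChangepointParams(),
) -> pd.DataFrame:
    """Fragment detection vs coverage on one classified clone.

    For each fraction, reads are subsampled without replacement (per-read
    classification is independent, so subsampling labels is equivalent to
    subsampling the reads) and both segmentations re-run. Reports the
    detected donor-fragment count and the mean coverage at each level.
    """
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise ValueError("fractions must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = len(classified.labels)
    rows = []
    for frac in fractions:
        if frac == 1.0:
            mask = np.ones(n, dtype=bool)
        else:
            keep = rng.choice(n, size=int(round(frac * n)), replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[keep] = True
        series = BinarySeries.from_classified(classified, read_mask=mask)
        frags_hmm = hmm_segment(series, hmm_params)
        freqs = site_frequencies(classified, read_mask=mask)
        frags_cp = changepoint_segment(freqs, cp_params)
        coverage = mask.sum() * classified.read_length / classified.genome_length
        rows.append(
            (frac, int(mask.sum()), coverage, len(frags_hmm), len(frags_cp))
        )
    return pd.DataFrame(
        rows, columns=["fraction", "n_reads", "mean_coverage", "n_fragments_hmm", "n_fragments_cp"]
    )


def write_fragments_bed(fragments: list[Fragment], path, chrom: str = "recipient") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for f in sorted(fragments, key=lambda f: f.start):
            name = f.origin + ("_marker" if f.contains_marker else "")
            fh.write(f"{chrom}\t{f.start}\t{f.end}\t{name}\t{f.n_obs}\n")
    return path
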