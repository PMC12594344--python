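"""Simple profile and fragment figures (matplotlib, Agg-safe)."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .pool import PoolProfile
from .segmentation import Fragment


def plot_pool_profile(profile: PoolProfile, marker: int | None = None, path=None):
    """Log10 donor/recipient ratio along the genome, marker highlighted."""
    fig, ax = plt.subplots(figsize=(9, 3))
    t = profile.table
    x = (t["bin_start"] + profile.bin_size / 2) / 1e6
    ax.plot(x, t["log_ratio"], lw=0.7, color="steelblue")
    if marker is not None:
        ax.axvline(marker / 1e6, color="crimson", lw=1, label="selected locus")
        ax.legend(frameon=False)
    ax.set_xlabel("recipient position (Mb)")
    ax.set_ylabel("log10 donor/recipient")
    fig.tight_layout()
    if path is not None:
        fig.savefig(Path(path), dpi=150)
        plt.close(fig)
    return fig


def plot_fragments(clones: dict[str, list[Fragment]], genome_length: int,
                   marker: int | None = None, path=None):
    """Donor fragments per clone as horizontal bars (one row per clone)."""
    fig, ax = plt.subplots(figsize=(9, 0.35 * max(len(clones), 4) + 1))
    for i, (cid, frags) in enumerate(clones.items()):
        for f in frags:
            ax.barh(i, (f.end - f.start) / 1e6, left=f.start / 1e6, height=0.6,
                    color="goldenrod" if f.contains_marker else "gray")
    if marker is not None:
        ax.axvline(marker / 1e6, color="crimson", lw=1)
    ax.set_yticks(range(len(clones)), list(clones))
    ax.set_xlim(0, genome_length / 1e6)
    ax.set_xlabel("recipient position (Mb)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(Path(path), dpi=150)
        plt.close(fig)
    return fig
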