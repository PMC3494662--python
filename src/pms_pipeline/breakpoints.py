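"""Sequencing-evidence characterization of a hemizygous deletion.

Three independent evidence lines, combined at the end:

* **Depth**: per-window coverage normalized by the genome median; maximal
  runs of a copy-state band (diploid / hemizygous / nullizygous) after light
  median smoothing give candidate segments — a hemizygous deletion shows a
  ratio near 0.5.
* **Discordant pairs**: read pairs whose observed insert exceeds the library
  insert distribution by ``z`` standard deviations bracket the junction.
* **Soft-clipped reads**: the consensus of clipped tails at the breakpoint
  reconstructs the junction at base resolution, including any non-template
  inserted bases between the retained flanks.

Coordinate convention: the reported flanks are the *retained* bases — the
last reference base before the deletion and the first after it — so the
deleted length is ``right_flank - left_flank - 1``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .datatypes import DepthProfile, PairEvidence, Region, SchemaError

#: copy-state bands on the depth ratio scale (lower-inclusive, upper-exclusive)
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "nullizygous": (0.0, 0.25),
    "hemizygous": (0.25, 0.75),
    "diploid": (0.75, float("inf")),
}


class NoJunctionError(ValueError):
    """No discordant-pair or clipped-read evidence for a junction."""


class AmbiguousJunctionError(ValueError):
    """Clipped-read consensus conflicts; junction cannot be resolved."""


def normalize_depth(profile: DepthProfile) -> pd.DataFrame:
    """Per-window ratio of raw depth to the genome median depth."""
    if profile.genome_median_depth <= 0:
        raise ValueError("genome_median_depth must be positive to normalize")
    out = profile.windows.copy()
    out["ratio"] = out["depth"] / profile.genome_median_depth
    return out


@dataclass(frozen=True)
class DepthSegment:
    chrom: str
    start: int
    end: int
    state: str
    mean_ratio: float
    n_windows: int

    def as_region(self) -> Region:
        return Region(self.chrom, self.start, self.end, self.state)


def _classify(ratio: np.ndarray, bands: dict[str, tuple[float, float]]) -> np.ndarray:
    states = np.empty(len(ratio), dtype=object)
    for name, (lo, hi) in bands.items():
        states[(ratio >= lo) & (ratio < hi)] = name
    return states


def segment_depth(
    ratio_profile: pd.DataFrame,
    *,
    bands: dict[str, tuple[float, float]] | None = None,
    min_windows: int = 5,
    smooth_windows: int = 5,
) -> list[DepthSegment]:
    """Copy-state segments from a normalized depth track.

    The ratio is median-smoothed over *smooth_windows* windows before
    banding; runs shorter than *min_windows* are absorbed into the preceding
    run (the following one at a chromosome start), which suppresses isolated
    noise and short assembly-artifact dips.
    """
    bands = bands or DEFAULT_BANDS
    segments: list[DepthSegment] = []
    for chrom, grp in ratio_profile.groupby("chrom", sort=False):
        ratio = grp["ratio"].to_numpy(dtype=float)
        raw_ratio = ratio.copy()
        if smooth_windows > 1 and len(ratio) >= smooth_windows:
            ratio = median_filter(ratio, size=smooth_windows, mode="nearest")
        states = _classify(ratio, bands)
        # run-length encode, then absorb short runs
        runs: list[list] = []  # [state, first_idx, last_idx]
        for i, st in enumerate(states):
            if runs and runs[-1][0] == st:
                runs[-1][2] = i
            else:
                runs.append([st, i, i])
        changed = True
        while changed and len(runs) > 1:
            changed = False
            for k, run in enumerate(runs):
                if run[2] - run[1] + 1 < min_windows:
                    target = k - 1 if k > 0 else k + 1
                    runs[target][1] = min(runs[target][1], run[1])
                    runs[target][2] = max(runs[target][2], run[2])
                    del runs[k]
                    # merge now-adjacent identical states
                    merged = [runs[0]]
                    for r in runs[1:]:
                        if merged[-1][0] == r[0]:
                            merged[-1][2] = r[2]
                        else:
                            merged.append(r)
                    runs = merged
                    changed = True
                    break
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        for st, i0, i1 in runs:
            segments.append(
                DepthSegment(
                    chrom=str(chrom),
                    start=int(starts[i0]),
                    end=int(ends[i1]),
                    state=str(st),
                    mean_ratio=float(np.mean(raw_ratio[i0 : i1 + 1])),
                    n_windows=int(i1 - i0 + 1),
                )
            )
    return segments


def locate_breakpoints_from_pairs(
    pairs: PairEvidence,
    insert_mean: float,
    insert_sd: float,
    *,
    z: float = 4.0,
) -> tuple[int, int]:
    """Bracket the junction from discordantly long, fully aligned pairs.

    Returns ``(max left-read end, min right-mate start)``: the innermost
    aligned bases on either side over all discordant pairs, which must
    enclose both breakpoint flanks. Raises :class:`NoJunctionError` when no
    pair is discordant.
    """
    t = pairs.table
    left_reads = (
        (t["clip_side"] == "none")
        & (t["mate_pos"] > t["pos"])
        & (t["insert"] > insert_mean + z * insert_sd)
    )
    sel = t.loc[left_reads]
    if sel.empty:
        raise NoJunctionError("no discordant read pairs")
    left_end = int((sel["pos"] + pairs.read_len - 1).max())
    right_start = int(sel["mate_pos"].min())
    return left_end, right_start


@dataclass(frozen=True)
class JunctionCall:
    """Base-resolution junction: retained flanks plus any inserted bases."""

    chrom: str
    left_flank: int
    right_flank: int
    inserted_seq: str
    support: int

    def __post_init__(self) -> None:
        if self.right_flank < self.left_flank + 2:
            raise SchemaError("right_flank must be >= left_flank + 2")

    @property
    def length_bp(self) -> int:
        return deletion_length(self.left_flank, self.right_flank)


def _consensus(seqs: list[str], threshold: float) -> str:
    """Per-column majority consensus of left-anchored strings.

    A column whose top base falls below *threshold* of its coverage raises
    :class:`AmbiguousJunctionError`; columns covered by a single read are
    taken as-is.
    """
    out = []
    n_cols = max(len(s) for s in seqs)
    for j in range(n_cols):
        bases = Counter(s[j] for s in seqs if len(s) > j)
        total = sum(bases.values())
        base, cnt = bases.most_common(1)[0]
        if total > 1 and cnt / total < threshold:
            raise AmbiguousJunctionError(
                f"consensus conflict at clipped column {j}: {dict(bases)}"
            )
        out.append(base)
    return "".join(out)


def assemble_junction(
    pairs: PairEvidence,
    reference_fetch: Callable[[int, int], str],
    bracket: tuple[int, int],
    *,
    min_support: int = 3,
    consensus_threshold: float = 0.6,
    max_insertion: int = 50,
) -> JunctionCall:
    """Reconstruct the junction from soft-clipped reads inside a bracket.

    Right-clipped reads vote for the left flank (their last aligned base);
    left-clipped reads vote for the right flank (their first aligned base).
    The consensus of right-clip tails is then split into non-template
    inserted bases and resumed reference sequence at the right flank. With no
    left-clipped reads the right flank is found by sliding the tail consensus
    along the reference within the bracket.
    """
    t = pairs.table
    lo, hi = bracket
    R = pairs.read_len
    # a read's clip point: last aligned base for right clips, first for left clips
    clip_len = t["clipped_seq"].str.len().fillna(0).astype(int)
    clip_point = np.where(
        t["clip_side"] == "right", t["pos"] + (R - clip_len) - 1, t["pos"]
    )
    clipped = t[
        (t["clip_side"] != "none") & (clip_point >= lo - 1) & (clip_point <= hi + 1)
    ]
    if len(clipped) < min_support:
        raise NoJunctionError(
            f"{len(clipped)} clipped reads in bracket; need >= {min_support}"
        )
    chrom = str(clipped["chrom"].iloc[0])

    right_clips = clipped[clipped["clip_side"] == "right"]
    left_clips = clipped[clipped["clip_side"] == "left"]
    if right_clips.empty:
        raise NoJunctionError("no right-clipped reads to anchor the left flank")

    # left flank: majority vote over last aligned bases of right-clipped reads
    last_aligned = right_clips["pos"] + (R - right_clips["clipped_seq"].str.len()) - 1
    left_flank, _ = Counter(int(v) for v in last_aligned).most_common(1)[0]
    tails = [
        str(row.clipped_seq)
        for row in right_clips.itertuples()
        if int(row.pos + (R - len(str(row.clipped_seq))) - 1) == left_flank
    ]
    tail_consensus = _consensus(tails, consensus_threshold)

    if not left_clips.empty:
        right_flank, _ = Counter(int(v) for v in left_clips["pos"]).most_common(1)[0]
        n_ins = _match_offset(tail_consensus, reference_fetch, right_flank)
    else:
        right_flank, n_ins = _scan_right_flank(
            tail_consensus, reference_fetch, left_flank, hi, max_insertion
        )
    inserted_seq = tail_consensus[:n_ins]
    return JunctionCall(
        chrom=chrom,
        left_flank=int(left_flank),
        right_flank=int(right_flank),
        inserted_seq=inserted_seq,
        support=int(len(clipped)),
    )


def _match_offset(
    consensus: str, fetch: Callable[[int, int], str], right_flank: int
) -> int:
    """Smallest k such that consensus[k:] equals reference from right_flank."""
    for k in range(len(consensus) + 1):
        rest = consensus[k:]
        if not rest:
            return k
        if fetch(right_flank, right_flank + len(rest) - 1) == rest:
            return k
    raise AmbiguousJunctionError(
        "clipped-tail consensus does not resume at the voted right flank"
    )


def _scan_right_flank(
    consensus: str,
    fetch: Callable[[int, int], str],
    left_flank: int,
    search_end: int,
    max_insertion: int,
) -> tuple[int, int]:
    """Slide the tail consensus along the reference to find (right_flank, k)."""
    for k in range(min(max_insertion, len(consensus) - 1) + 1):
        rest = consensus[k:]
        if len(rest) < 10:  # too short to place uniquely
            break
        for p in range(left_flank + 2, search_end + 2):
            if fetch(p, p + len(rest) - 1) == rest:
                return p, k
    raise AmbiguousJunctionError("could not place clipped-tail consensus in reference")


def deletion_length(left_flank: int, right_flank: int) -> int:
    """Deleted bases between two retained flanks (open interval)."""
    if right_flank < left_flank + 2:
        raise ValueError(
            f"flanks ({left_flank}, {right_flank}) enclose no deleted base"
        )
    return right_flank - left_flank - 1


@dataclass
class DeletionCall:
    """Merged deletion call across depth and junction evidence."""

    chrom: str
    interval: Region
    length_bp: int
    junction: JunctionCall | None = None
    segment: DepthSegment | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.flags


def merge_evidence(
    segments: list[DepthSegment], junction: JunctionCall | None
) -> DeletionCall:
    """Combine depth segments with a junction call into one deletion call.

    Junction coordinates take precedence (base resolution). A junction
    without an overlapping hemizygous depth segment — or a hemizygous
    segment without a junction — yields a flagged, lower-confidence call.
    """
    hemi = [s for s in segments if s.state == "hemizygous"]
    if junction is not None:
        interval = Region(
            junction.chrom, junction.left_flank + 1, junction.right_flank - 1, "deletion"
        )
        overlapping = [
            s for s in hemi if s.chrom == junction.chrom and s.as_region().overlaps(interval)
        ]
        flags = [] if overlapping else ["discordant_evidence"]
        return DeletionCall(
            chrom=junction.chrom,
            interval=interval,
            length_bp=junction.length_bp,
            junction=junction,
            segment=overlapping[0] if overlapping else (hemi[0] if hemi else None),
            flags=flags,
        )
    if not hemi:
        raise NoJunctionError("no junction and no hemizygous depth segment")
    best = max(hemi, key=lambda s: s.n_windows)
    interval = best.as_region()
    return DeletionCall(
        chrom=best.chrom,
        interval=interval,
        length_bp=interval.length,
        junction=None,
        segment=best,
        flags=["window_resolution"],
    )
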