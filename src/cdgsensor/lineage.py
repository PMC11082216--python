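"""Post-tracking single-cell lineage quality control and classification.

Automated tracking of dividing bacteria produces occasional segmentation and
linking errors. This module implements the screening procedure used for
sister-cell analyses of c-di-GMP dynamics: sisters are paired by parent and
trimmed to a common length, then pairs are excluded when (i) they are tracked
for fewer than a species-dependent minimum number of frames, (ii) either
sister shows an implausible frame-to-frame length jump, or (iii) the summed
birth length of the sisters deviates strongly from the mother's final length.
Retained pairs are split into a c-di-GMP-high and a c-di-GMP-low class by
their lifetime-mean FITC intensity, and tracks can be overlaid on a common
time axis anchored at each cell's intensity minimum.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError, MalformedLineageError, TieBreakWarning

TRACK_COLUMNS = ("frame", "time_min", "length_um", "fitc_mean")


@dataclass
class CellTrack:
    """Per-frame record of one tracked cell.

    ``data`` holds columns ``frame, time_min, length_um, fitc_mean`` with
    consecutive frames; the first record is the birth frame.
    """

    cell_id: str
    data: pd.DataFrame
    parent_id: str | None = None
    species_profile: str = "caulobacter"

    def __post_init__(self):
        missing = set(TRACK_COLUMNS) - set(self.data.columns)
        if missing:
            raise InvalidParameterError(f"track {self.cell_id} lacks columns {sorted(missing)}")
        frames = self.data["frame"].to_numpy()
        if len(frames) and not np.array_equal(frames, np.arange(frames[0], frames[0] + len(frames))):
            raise InvalidParameterError(f"track {self.cell_id} has non-consecutive frames")
        if (self.data["length_um"] <= 0).any():
            raise InvalidParameterError(f"track {self.cell_id} has non-positive lengths")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def birth_length(self) -> float:
        return float(self.data["length_um"].iloc[0])

    @property
    def final_length(self) -> float:
        return float(self.data["length_um"].iloc[-1])

    @property
    def mean_fitc(self) -> float:
        return float(self.data["fitc_mean"].mean())

    def trimmed(self, n: int) -> "CellTrack":
        return CellTrack(self.cell_id, self.data.iloc[:n].reset_index(drop=True),
                         self.parent_id, self.species_profile)


@dataclass
class SisterPair:
    """Two sister tracks trimmed to a common frame count."""

    track_a: CellTrack
    track_b: CellTrack
    mother_final_length: float | None = None

    @property
    def trimmed_length(self) -> int:
        return self.track_a.n_frames


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the three exclusion filters.

    ``min_frames``: minimum trimmed track length; ``jump_*_max``: maximal
    tolerated frame-to-frame relative length decrease/increase;
    ``division_*_max``: maximal tolerated relative mismatch between summed
    sister birth lengths and the mother's final length.
    """

    min_frames: int = 12
    jump_decrease_max: float = 0.08
    jump_increase_max: float = 0.08
    division_decrease_max: float = 0.06
    division_increase_max: float = 0.20

    def __post_init__(self):
        fr = (self.jump_decrease_max, self.jump_increase_max,
              self.division_decrease_max, self.division_increase_max)
        if not all(0 < v < 1 for v in fr):
            raise InvalidParameterError("all filter fractions must be in (0, 1)")
        if self.min_frames < 2:
            raise InvalidParameterError("min_frames must be >= 2")

    @classmethod
    def caulobacter(cls) -> "FilterConfig":
        """C. crescentus preset: >= 12 frames (1 h at 5-min frames), 8%/8% jumps."""
        return cls(min_frames=12, jump_increase_max=0.08)

    @classmethod
    def pseudomonas(cls) -> "FilterConfig":
        """P. aeruginosa preset: >= 8 frames (40 min), 8% down / 12% up jumps."""
        return cls(min_frames=8, jump_increase_max=0.12)

    @classmethod
    def for_profile(cls, profile: str) -> "FilterConfig":
        try:
            return {"caulobacter": cls.caulobacter, "pseudomonas": cls.pseudomonas}[profile]()
        except KeyError:
            raise InvalidParameterError(f"unknown species profile {profile!r}") from None


def tracks_from_table(table: pd.DataFrame, species_profile: str = "caulobacter") -> list:
    """Build CellTrack objects from a long table with columns
    ``cell_id, parent_id, frame, time_min, length_um, fitc_mean``."""
    tracks = []
    for cid, grp in table.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame").reset_index(drop=True)
        parent = grp["parent_id"].iloc[0]
        parent = None if pd.isna(parent) or parent in ("", "none") else str(parent)
        tracks.append(
            CellTrack(str(cid), grp[list(TRACK_COLUMNS)].copy(), parent, species_profile)
        )
    return tracks


def pair_and_trim(tracks: list) -> list:
    """Pair each parent's two tracked children and trim both to the shorter
    sister's frame count. Parents with a single tracked child yield no pair;
    more than two children raise :class:`MalformedLineageError`.
    """
    by_id = {t.cell_id: t for t in tracks}
    children: dict = {}
    for t in tracks:
        if t.parent_id is not None:
            children.setdefault(t.parent_id, []).append(t)
    pairs = []
    for parent_id in sorted(children):
        sibs = sorted(children[parent_id], key=lambda t: t.cell_id)
        if len(sibs) > 2:
            raise MalformedLineageError(
                f"parent {parent_id} has {len(sibs)} tracked children"
            )
        if len(sibs) < 2:
            continue
        a, b = sibs
        n = min(a.n_frames, b.n_frames)
        mother = by_id.get(parent_id)
        pairs.append(
            SisterPair(a.trimmed(n), b.trimmed(n),
                       mother.final_length if mother is not None else None)
        )
    return pairs


def _max_jumps(track: CellTrack):
    """Largest relative frame-to-frame decrease and increase in length.
    The denominator is the earlier frame's length."""
    L = track.data["length_um"].to_numpy()
    if L.size < 2:
        return 0.0, 0.0
    rel = np.diff(L) / L[:-1]
    return float(-rel.min()) if rel.min() < 0 else 0.0, float(rel.max()) if rel.max() > 0 else 0.0


def filter_pairs(pairs: list, config: FilterConfig):
    """Apply the three exclusion filters to trimmed sister pairs.

    Returns ``(retained, rejections)`` where ``rejections`` is a list of
    ``(pair, reasons)`` with every violated rule named:
    ``short_track``, ``length_jump``, ``division_inconsistent``.
    Filtering has set semantics: it is idempotent, order-independent, and
    relaxing any threshold can only grow the retained set.
    """
    retained, rejections = [], []
    for pair in pairs:
        reasons = []
        if pair.trimmed_length < config.min_frames:
            reasons.append("short_track")
        for tr in (pair.track_a, pair.track_b):
            dec, inc = _max_jumps(tr)
            if dec > config.jump_decrease_max or inc > config.jump_increase_max:
                reasons.append("length_jump")
                break
        if pair.mother_final_length is None:
            warnings.warn(
                "mother final length unavailable; division-consistency rule skipped"
            )
        else:
            summed = pair.track_a.birth_length + pair.track_b.birth_length
            rel = (summed - pair.mother_final_length) / pair.mother_final_length
            if rel < -config.division_decrease_max or rel > config.division_increase_max:
                reasons.append("division_inconsistent")
        if reasons:
            rejections.append((pair, reasons))
        else:
            retained.append(pair)
    return retained, rejections


def classify_high_low(pair: SisterPair) -> dict:
    """Label the sister with the greater lifetime-mean FITC intensity as
    c-di-GMP-high and the other as low. Exact ties break lexicographically
    by cell id with a :class:`TieBreakWarning`."""
    ma, mb = pair.track_a.mean_fitc, pair.track_b.mean_fitc
    if ma == mb:
        warnings.warn(
            f"equal lifetime means for {pair.track_a.cell_id}/{pair.track_b.cell_id}; "
            "breaking tie lexicographically",
            TieBreakWarning,
        )
        high, low = sorted((pair.track_a, pair.track_b), key=lambda t: t.cell_id)
    elif ma > mb:
        high, low = pair.track_a, pair.track_b
    else:
        high, low = pair.track_b, pair.track_a
    return {
        "high": high.cell_id,
        "low": low.cell_id,
        "mean_high": max(ma, mb),
        "mean_low": min(ma, mb),
    }


def align_to_minimum(tracks: list, confidence: float = 0.95):
    """Overlay tracks on a relative time axis anchored at each cell's
    intensity minimum (t = 0 at the frame of minimum FITC signal; ties
    resolve to the earliest frame).

    Returns ``(long, summary)``: a long table of
    ``cell_id, rel_time_min, fitc_mean`` and a per-time summary with the
    across-track mean and a t-distribution confidence band.
    """
    rows = []
    for t in tracks:
        if t.n_frames < 3:
            raise InvalidParameterError(f"track {t.cell_id}: need >= 3 frames to align")
        fitc = t.data["fitc_mean"].to_numpy()
        tmin = t.data["time_min"].to_numpy()
        anchor = tmin[int(np.argmin(fitc))]
        rows.append(pd.DataFrame({
            "cell_id": t.cell_id,
            "rel_time_min": tmin - anchor,
            "fitc_mean": fitc,
        }))
    long = pd.concat(rows, ignore_index=True)

    def _summ(g):
        n = len(g)
        m = g["fitc_mean"].mean()
        if n > 1:
            sem = g["fitc_mean"].std(ddof=1) / np.sqrt(n)
            h = stats.t.ppf(0.5 + confidence / 2, n - 1) * sem
        else:
            h = np.nan
        return pd.Series({"mean": m, "ci_lo": m - h, "ci_hi": m + h, "n": n})

    summary = (
        long.groupby("rel_time_min").apply(_summ, include_groups=False).reset_index()
    )
    return long, summary
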