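"""Per-core detection counts and the multiplicity-of-three trimer binning.

After symmetry expansion, every physical 3-fold site of a core appears
in three expanded sub-particles (the order of its stabilizer), so a
bound CBD trimer that is detected perfectly contributes exactly three
occupied regions.  Detections are mapped back to their parent core,
counted, and grouped into bins of three — counts of 8, 9 or 10 most
likely signify 3 bound trimers — to estimate the number of trimers per
core.  Cores binned above a plausibility ceiling (default 4, the steric
maximum) are kept but annotated as probable false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MAX_DETECTIONS",
    "OccupancySummary",
    "mapback_count",
    "bin_detections",
    "occupancy_summary",
]

#: Expanded regions per core under icosahedral expansion.
MAX_DETECTIONS = 60

#: Trimer counts above this are annotated as probable false positives.
DEFAULT_PLAUSIBILITY_CEILING = 4


def mapback_count(
    flags: pd.DataFrame,
    known_cores: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Count occupied sub-particles per core.

    *flags* needs columns ``core_id`` and boolean ``occupied`` (one row
    per expanded sub-particle).  If *known_cores* is given, every flag
    row must reference one of those cores; orphans are rejected with the
    offending ids listed.  Cores present in *known_cores* but carrying no
    flagged rows report zero detections.

    Returns a table with one row per core: ``core_id, detection_count``.
    """
    for col in ("core_id", "occupied"):
        if col not in flags.columns:
            raise ValueError(f"flags table is missing column {col!r}")
    if known_cores is not None:
        known = pd.Index(pd.unique(pd.Series(known_cores)))
        orphans = pd.Index(flags["core_id"].unique()).difference(known)
        if len(orphans) > 0:
            raise ValueError(
                f"{len(orphans)} sub-particle core ids not in the parent table: "
                f"{sorted(orphans.tolist())[:10]}"
            )
    counts = (
        flags.groupby("core_id", sort=True)["occupied"]
        .sum()
        .astype(int)
        .rename("detection_count")
    )
    if known_cores is not None:
        counts = counts.reindex(known.sort_values(), fill_value=0)
        counts.index.name = "core_id"
    out = counts.reset_index()
    bad = out[out["detection_count"] > MAX_DETECTIONS]
    if len(bad):
        raise ValueError(
            f"cores with more than {MAX_DETECTIONS} detections: {bad['core_id'].tolist()[:10]}"
        )
    return out


def bin_detections(d):
    """Group a detection count into its most likely trimer number.

    ``t = floor((d + 1) / 3)``: the bin for t trimers covers detection
    counts {3t-1, 3t, 3t+1}, so 8, 9 and 10 all signify 3 trimers.  The
    lowest bin {0, 1} is asymmetric — a single stray detection still
    reads as zero trimers.  Accepts scalars or arrays.
    """
    arr = np.asarray(d)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValueError("detection counts must be integers")
        arr = arr.astype(int)
    if np.any(arr < 0) or np.any(arr > MAX_DETECTIONS):
        raise ValueError(f"detection counts must lie in 0..{MAX_DETECTIONS}")
    t = (arr + 1) // 3
    return int(t) if np.isscalar(d) or np.ndim(d) == 0 else t


@dataclass(frozen=True)
class OccupancySummary:
    """Histograms of raw detections and binned trimer counts over cores."""

    n_cores: int
    detection_hist: dict[int, int]            # raw d -> number of cores
    trimer_hist: dict[int, int]               # binned t -> number of cores
    trimer_fractions: dict[int, float]
    frac_at_least: dict[int, float]           # threshold k -> fraction with t >= k
    plausibility_ceiling: int
    implausible_cores: int = 0                # cores binned above the ceiling
    notes: tuple[str, ...] = field(default=())

    def fraction_percent(self, k: int, ndigits: int | None = 0) -> float:
        """Percentage of cores with at least *k* trimers (rounded for headlines)."""
        pct = 100.0 * self.frac_at_least[k]
        return round(pct, ndigits) if ndigits is not None else pct


def occupancy_summary(
    detections: pd.DataFrame,
    at_least: tuple[int, ...] = (1, 5),
    plausibility_ceiling: int = DEFAULT_PLAUSIBILITY_CEILING,
) -> OccupancySummary:
    """Summarize a per-core detection table into trimer-count statistics.

    Raw counts are binned with :func:`bin_detections`; cores whose binned
    count exceeds *plausibility_ceiling* are counted and annotated as
    probable false positives (the steric model caps real occupancy), but
    never dropped.  ``frac_at_least[k]`` gives the fraction of cores with
    k or more trimers assigned.
    """
    if "detection_count" not in detections.columns:
        raise ValueError("detection table is missing column 'detection_count'")
    if len(detections) == 0:
        raise ValueError("detection table is empty")
    if detections["core_id"].duplicated().any():
        raise ValueError("detection table has duplicate core_id rows")
    d = detections["detection_count"].to_numpy()
    t = bin_detections(d)
    n = len(d)

    det_hist = {int(v): int(c) for v, c in zip(*np.unique(d, return_counts=True))}
    tri_hist = {int(v): int(c) for v, c in zip(*np.unique(t, return_counts=True))}
    fractions = {k: c / n for k, c in tri_hist.items()}
    frac_ge = {int(k): float(np.mean(t >= k)) for k in at_least}

    implausible = int(np.count_nonzero(t > plausibility_ceiling))
    notes = []
    if implausible:
        notes.append(
            f"{implausible} core(s) binned above the plausibility ceiling of "
            f"{plausibility_ceiling} trimers; attributed to false-positive "
            "identification, retained in all histograms"
        )
    return OccupancySummary(
        n_cores=n,
        detection_hist=det_hist,
        trimer_hist=tri_hist,
        trimer_fractions=fractions,
        frac_at_least=frac_ge,
        plausibility_ceiling=plausibility_ceiling,
        implausible_cores=implausible,
        notes=tuple(notes),
    )
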