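"""Translocation kinetics and population-fraction arithmetic.

Per-cell translocation time is the interval between the first detected
YFP frame (origin region captured in the forespore) and the first
detected CFP frame (reporter locus translocated across the septum).
Population assays count, per field of view and timepoint, the YFP+
forespores and the CFP+YFP+ subset; the CFP+/YFP+ fraction tracks
translocation progress, and mutant-vs-wild-type ratios of that fraction
give the efficiency of transport.  CFP-only forespores (no detectable
YFP) are tallied separately and excluded from the fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .detect import OnsetCall, detect_reporter_onset
from .simulate import TimelapseResult

log = logging.getLogger(__name__)

COMPLETE = "complete"
YFP_ONLY_CENSORED = "yfp_only_censored"
CFP_ONLY_EXCLUDED = "cfp_only_excluded"

__all__ = [
    "TranslocationEvent",
    "TranslocationSummary",
    "EfficiencyResult",
    "per_cell_translocation_time",
    "translocation_time_distribution",
    "population_fractions",
    "efficiency_of_transport",
    "cfp_only_fraction",
    "sporulation_efficiency",
    "SporulationEfficiency",
    "events_from_timelapse",
    "counts_from_onsets",
]


@dataclass
class TranslocationEvent:
    cell_id: int
    t_yfp: Optional[float]  # min
    t_cfp: Optional[float]
    delta_t: Optional[float]
    classification: str


@dataclass
class TranslocationSummary:
    n: int
    mean_min: float
    bin_edges_min: np.ndarray
    fractions: np.ndarray  # histogram normalised to fractions of complete events


@dataclass
class EfficiencyResult:
    timepoint: Optional[float]
    fraction_mutant: float
    fraction_wt: float
    efficiency: float
    fold_change: Optional[float] = None
    sd_across_fields: Optional[float] = None


def per_cell_translocation_time(
    yfp: Optional[OnsetCall], cfp: Optional[OnsetCall]
) -> Optional[TranslocationEvent]:
    """Classify one cell's onset pair into a translocation event.

    Complete events carry delta_t = t_cfp - t_yfp.  YFP without CFP is
    censored; CFP without YFP (or CFP before YFP) is the excluded
    mis-capture class.  Returns ``None`` (with a logged reason) when both
    channels are censored.
    """
    t_y = None if yfp is None or yfp.censored else yfp.onset_time
    t_c = None if cfp is None or cfp.censored else cfp.onset_time
    cell_id = (yfp or cfp).cell_id if (yfp or cfp) else -1
    if t_y is None and t_c is None:
        log.debug("cell %s dropped: both reporters censored", cell_id)
        return None
    if t_y is None:
        return TranslocationEvent(cell_id, None, t_c, None, CFP_ONLY_EXCLUDED)
    if t_c is None:
        return TranslocationEvent(cell_id, t_y, None, None, YFP_ONLY_CENSORED)
    if t_c < t_y:
        return TranslocationEvent(cell_id, t_y, t_c, None, CFP_ONLY_EXCLUDED)
    return TranslocationEvent(cell_id, t_y, t_c, t_c - t_y, COMPLETE)


def translocation_time_distribution(
    events: Sequence[TranslocationEvent], bin_width: float = 2.0
) -> TranslocationSummary:
    """Histogram (as fractions of complete events) and mean of delta_t."""
    deltas = np.array(
        [e.delta_t for e in events if e is not None and e.classification == COMPLETE],
        dtype=float,
    )
    if deltas.size == 0:
        raise ValueError("no complete translocation events")
    top = max(float(deltas.max()), bin_width)
    edges = np.arange(0.0, np.ceil(top / bin_width) * bin_width + bin_width, bin_width)
    counts, edges = np.histogram(deltas, bins=edges)
    return TranslocationSummary(
        n=int(deltas.size),
        mean_min=float(np.mean(deltas)),
        bin_edges_min=edges,
        fractions=counts / deltas.size,
    )


def population_fractions(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-timepoint CFP+/YFP+ fraction, mean and sd across fields of view.

    ``counts`` columns: timepoint, field_id, n_yfp_pos, n_cfp_and_yfp
    (n_cfp_only optional).  Fields with zero YFP+ forespores are excluded
    with a warning; a timepoint with no usable field raises.
    """
    required = {"timepoint", "field_id", "n_yfp_pos", "n_cfp_and_yfp"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    if (counts["n_cfp_and_yfp"] > counts["n_yfp_pos"]).any():
        raise ValueError("n_cfp_and_yfp cannot exceed n_yfp_pos")
    if (counts[["n_yfp_pos", "n_cfp_and_yfp"]] < 0).any().any():
        raise ValueError("counts must be >= 0")
    out = []
    for timepoint, grp in counts.groupby("timepoint"):
        usable = grp[grp["n_yfp_pos"] > 0]
        dropped = len(grp) - len(usable)
        if dropped:
            log.warning(
                "timepoint %s: excluded %d field(s) with zero YFP+ forespores",
                timepoint,
                dropped,
            )
        if usable.empty:
            raise ValueError(f"all fields at timepoint {timepoint} have zero YFP+")
        fr = usable["n_cfp_and_yfp"] / usable["n_yfp_pos"]
        out.append(
            {
                "timepoint": timepoint,
                "n_fields": len(usable),
                "fraction_mean": float(fr.mean()),
                "fraction_sd": 0.0 if len(fr) == 1 else float(fr.std(ddof=1)),
            }
        )
    return pd.DataFrame(out)


def efficiency_of_transport(
    fraction_mutant: float,
    fraction_wt: float,
    timepoint: Optional[float] = None,
    reference_deficit: Optional[float] = None,
    sd_across_fields: Optional[float] = None,
) -> EfficiencyResult:
    """Mutant CFP+/YFP+ fraction normalised to wild type at one timepoint.

    ``reference_deficit`` (e.g. the wild-type-motor deficit) turns the
    deficit 1 - efficiency into a fold change relative to that baseline.
    """
    if fraction_wt <= 0:
        raise ValueError("efficiency undefined: wild-type fraction must be > 0")
    if fraction_mutant < 0:
        raise ValueError("fractions must be >= 0")
    eff = fraction_mutant / fraction_wt
    fold = None
    if reference_deficit is not None and reference_deficit > 0:
        fold = (1.0 - eff) / reference_deficit
    return EfficiencyResult(
        timepoint=timepoint,
        fraction_mutant=fraction_mutant,
        fraction_wt=fraction_wt,
        efficiency=eff,
        fold_change=fold,
        sd_across_fields=sd_across_fields,
    )


def cfp_only_fraction(n_cfp_only: int, n_cfp_and_yfp: int) -> float:
    """Fraction of CFP+ forespores lacking detectable YFP."""
    if n_cfp_only < 0 or n_cfp_and_yfp < 0:
        raise ValueError("counts must be >= 0")
    total = n_cfp_only + n_cfp_and_yfp
    if total == 0:
        raise ValueError("no CFP+ forespores")
    return n_cfp_only / total


@dataclass
class SporulationEfficiency:
    condition: str
    efficiency: float  # spores / reference CFU
    sd: float
    n_dilutions: int
    reference_cfu: float


def sporulation_efficiency(
    cfu: pd.DataFrame,
    condition: str,
    reference_condition: str = "wild_type",
    normalization: str = "resuspension",
    countable_range: Sequence[float] = (30, 300),
) -> SporulationEfficiency:
    """Heat-kill CFU arithmetic: spores as a fraction of reference CFU.

    ``cfu`` columns: condition, stage, dilution, colonies.  Stages are
    ``resuspension``, ``pre_heat_kill``, ``post_heat_kill``.  Spores =
    post-heat-kill colonies x dilution; the denominator is the reference
    condition's CFU at the ``normalization`` stage.  Only plates whose
    colony count lies within ``countable_range`` (inclusive) enter, except
    that an all-zero post-heat-kill count is honoured as efficiency 0.
    The mean and sd are taken across countable dilutions.
    """
    required = {"condition", "stage", "dilution", "colonies"}
    missing = required - set(cfu.columns)
    if missing:
        raise ValueError(f"cfu table missing columns: {sorted(missing)}")
    lo, hi = countable_range

    ref = cfu[(cfu["condition"] == reference_condition) & (cfu["stage"] == normalization)]
    ref = ref[(ref["colonies"] >= lo) & (ref["colonies"] <= hi)]
    if ref.empty:
        raise ValueError(
            f"no countable {normalization} dilution for reference condition "
            f"{reference_condition!r}"
        )
    reference_cfu = float((ref["colonies"] * ref["dilution"]).mean())

    post = cfu[(cfu["condition"] == condition) & (cfu["stage"] == "post_heat_kill")]
    if post.empty:
        raise ValueError(f"no post-heat-kill counts for condition {condition!r}")
    countable = post[(post["colonies"] >= lo) & (post["colonies"] <= hi)]
    if countable.empty:
        if (post["colonies"] == 0).all():
            return SporulationEfficiency(condition, 0.0, 0.0, int(len(post)), reference_cfu)
        raise ValueError(f"no countable post-heat-kill dilution for {condition!r}")
    eff = (countable["colonies"] * countable["dilution"]) / reference_cfu
    sd = 0.0 if len(eff) == 1 else float(eff.std(ddof=1))
    return SporulationEfficiency(
        condition=condition,
        efficiency=float(eff.mean()),
        sd=sd,
        n_dilutions=int(len(eff)),
        reference_cfu=reference_cfu,
    )


# --------------------------------------------------------------------------
# bridges from simulated time-lapse data


def events_from_timelapse(
    sim: TimelapseResult,
    threshold_multiplier: float = 2.0,
) -> List[Optional[TranslocationEvent]]:
    """Run onset detection on every simulated trace and classify each cell.

    Background statistics come from the generator configuration (the
    cell-free background the real assay would sample).
    """
    k = sim.kinetics
    events: List[Optional[TranslocationEvent]] = []
    for i in range(sim.yfp.shape[0]):
        y_call = detect_reporter_onset(
            sim.yfp[i],
            k.background_level,
            k.detection_noise,
            k.frame_interval,
            cell_id=i,
            channel="YFP",
            threshold_multiplier=threshold_multiplier,
        )
        c_call = detect_reporter_onset(
            sim.cfp[i],
            k.background_level,
            k.detection_noise,
            k.frame_interval,
            cell_id=i,
            channel="CFP",
            threshold_multiplier=threshold_multiplier,
        )
        events.append(per_cell_translocation_time(y_call, c_call))
    return events


def counts_from_onsets(
    events: Sequence[Optional[TranslocationEvent]],
    timepoints: Sequence[float],
    n_fields: int = 5,
) -> pd.DataFrame:
    """Tally PopulationCounts per field and timepoint from per-cell events.

    Cells are split into ``n_fields`` contiguous fields of view.  At each
    timepoint T a cell is YFP+ if its YFP onset time is <= T, CFP+YFP+ if
    both onsets are <= T, and CFP-only if CFP is on but YFP never was.
    """
    cells = [e for e in events if e is not None]
    fields = np.array_split(np.arange(len(cells)), n_fields)
    rows = []
    for T in timepoints:
        for field_id, idx in enumerate(fields):
            n_y = n_cy = n_co = 0
            for i in idx:
                e = cells[i]
                y_on = e.t_yfp is not None and e.t_yfp <= T
                c_on = e.t_cfp is not None and e.t_cfp <= T
                if y_on:
                    n_y += 1
                    if c_on:
                        n_cy += 1
                elif c_on:
                    n_co += 1
            rows.append(
                {
                    "timepoint": T,
                    "field_id": field_id,
                    "n_yfp_pos": n_y,
                    "n_cfp_and_yfp": n_cy,
                    "n_cfp_only": n_co,
                }
            )
    return pd.DataFrame(rows)
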