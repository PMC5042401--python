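"""Multiplexed isotopic-label relative quantification.

The labeling design tags each replicate culture with one isotopic amine
label (e.g. D0/D3/D6/D9 variants of the TMAB tag) so that two control and
two treated biological replicates co-elute in one LC-MS run.  Peptide levels
are quantified from monoisotopic peak intensities: intensities of multiple
charge states are averaged, each channel is expressed relative to the mean
of the control channels of the same run, per-run ratios are pooled across
runs, and control vs treated ratios are compared with a two-sided Student's
(pooled-variance) t-test.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Group",
    "Tier",
    "FoldClass",
    "ChannelDesign",
    "IntensityObservation",
    "RelativeLevelSet",
    "DifferentialResult",
    "average_charge_states",
    "relative_levels",
    "pool_and_test",
    "differential_table",
    "rank_plot_data",
    "fold_change_tally",
]

#: Sentinel charge for "charge states combined".
COMBINED_CHARGE = 0

#: Default significance thresholds (raw p), highest tier last.
TIER_THRESHOLDS = (0.05, 0.01, 0.001)


class Group(enum.Enum):
    CONTROL = "CONTROL"
    TREATED = "TREATED"


class Tier(enum.Enum):
    """Significance tier from the raw t-test p-value."""

    NS = "NS"
    P05 = "P05"
    P01 = "P01"
    P001 = "P001"


class FoldClass(enum.Enum):
    """2-fold-change call on the pooled treated mean (strict thresholds)."""

    UP_2X = "UP_2X"
    DOWN_2X = "DOWN_2X"
    WITHIN = "WITHIN"


@dataclass(frozen=True)
class ChannelDesign:
    """Labeling scheme of one LC-MS run: channel -> group / replicate."""

    run_id: str
    channels: tuple[str, ...]
    group_of: Mapping[str, Group]
    replicate_of: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError(f"duplicate channel names in run {self.run_id!r}")
        for ch in self.channels:
            if ch not in self.group_of:
                raise ValueError(f"channel {ch!r} has no group in run {self.run_id!r}")
        if not any(self.group_of[c] is Group.CONTROL for c in self.channels):
            raise ValueError(f"run {self.run_id!r} has no CONTROL channel")

    def control_channels(self) -> list[str]:
        return [c for c in self.channels if self.group_of[c] is Group.CONTROL]

    def treated_channels(self) -> list[str]:
        return [c for c in self.channels if self.group_of[c] is Group.TREATED]

    @staticmethod
    def two_by_two(run_id: str, channels: Sequence[str] = ("D0", "D3", "D6", "D9")):
        """The standard 4-plex design: first two channels control, last two treated."""
        if len(channels) != 4:
            raise ValueError("two_by_two expects exactly 4 channels")
        group_of = {
            channels[0]: Group.CONTROL,
            channels[1]: Group.CONTROL,
            channels[2]: Group.TREATED,
            channels[3]: Group.TREATED,
        }
        replicate_of = {
            channels[0]: "c1",
            channels[1]: "c2",
            channels[2]: "t1",
            channels[3]: "t2",
        }
        return ChannelDesign(run_id, tuple(channels), group_of, replicate_of)


@dataclass(frozen=True)
class IntensityObservation:
    """Per-channel monoisotopic peak intensities for one peptide in one run.

    ``peptide_key`` is ``(sequence, modification signature)``; a channel
    absent from ``intensity_by_channel`` was not detected (ND).
    """

    peptide_key: tuple[str, str]
    run_id: str
    charge: int
    intensity_by_channel: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.charge < 0:
            raise ValueError("charge must be >= 1 (0 reserved for combined)")
        if not self.intensity_by_channel:
            raise ValueError("at least one channel must be present")
        for ch, v in self.intensity_by_channel.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"intensity for channel {ch!r} must be finite, >= 0")


@dataclass(frozen=True)
class RelativeLevelSet:
    """Per-channel ratios to the control mean for one peptide in one run."""

    peptide_key: tuple[str, str]
    run_id: str
    ratio_by_channel: Mapping[str, float]


@dataclass(frozen=True)
class DifferentialResult:
    """Pooled control vs treated comparison for one peptide (one table row)."""

    peptide_key: tuple[str, str]
    gene: str
    control_mean: float
    control_sem: float
    n_control: int
    treated_mean: float
    treated_sem: float
    n_treated: int
    p_value: float | None
    tier: Tier
    fold_class: FoldClass
    degenerate: bool = False
    insufficient: bool = False


def average_charge_states(
    observations: Sequence[IntensityObservation],
) -> IntensityObservation:
    """Collapse multiple charge states of one peptide in one run.

    Per channel, the arithmetic mean over the charge states in which that
    channel was detected; the combined observation carries charge 0.
    """
    if not observations:
        raise ValueError("no observations to average")
    key = observations[0].peptide_key
    run = observations[0].run_id
    for obs in observations:
        if obs.peptide_key != key or obs.run_id != run:
            raise ValueError("observations must share peptide_key and run_id")
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for obs in observations:
        for ch, v in obs.intensity_by_channel.items():
            sums[ch] = sums.get(ch, 0.0) + v
            counts[ch] = counts.get(ch, 0) + 1
    combined = {ch: sums[ch] / counts[ch] for ch in sums}
    return IntensityObservation(key, run, COMBINED_CHARGE, combined)


def relative_levels(
    obs: IntensityObservation, design: ChannelDesign
) -> RelativeLevelSet:
    """Express each detected channel relative to the run's control mean.

    The denominator is the arithmetic mean of the intensities of the
    *detected* control channels, so when both controls are present the mean
    of the two control ratios is exactly 1 by construction.  Undetected
    channels stay ND (absent from the result).
    """
    if obs.run_id != design.run_id:
        raise ValueError("observation and design refer to different runs")
    controls = [
        obs.intensity_by_channel[c]
        for c in design.control_channels()
        if c in obs.intensity_by_channel
    ]
    if not controls:
        raise ValueError(
            f"peptide {obs.peptide_key} unquantifiable in run {obs.run_id}: "
            "no control channel detected"
        )
    denom = sum(controls) / len(controls)
    if denom <= 0:
        raise ValueError("control mean intensity is zero; ratios undefined")
    ratios = {ch: v / denom for ch, v in obs.intensity_by_channel.items()}
    return RelativeLevelSet(obs.peptide_key, obs.run_id, ratios)


def _tier(p: float | None, thresholds: Sequence[float] = TIER_THRESHOLDS) -> Tier:
    if p is None:
        return Tier.NS
    t05, t01, t001 = thresholds
    if p < t001:
        return Tier.P001
    if p < t01:
        return Tier.P01
    if p < t05:
        return Tier.P05
    return Tier.NS


def _fold_class(treated_mean: float, threshold: float = 2.0) -> FoldClass:
    # strict inequalities: a ratio of exactly 2 or exactly 1/2 is WITHIN
    if treated_mean > threshold:
        return FoldClass.UP_2X
    if treated_mean < 1.0 / threshold:
        return FoldClass.DOWN_2X
    return FoldClass.WITHIN


def pool_and_test(
    levels: Sequence[RelativeLevelSet],
    design_by_run: Mapping[str, ChannelDesign],
    gene: str = "",
    fold_threshold: float = 2.0,
    tier_thresholds: Sequence[float] = TIER_THRESHOLDS,
) -> DifferentialResult:
    """Pool per-run ratios across runs and test control vs treated.

    Control ratios from every run are merged into one control group (the
    pooled n is the total number of control replicates in which the peptide
    was detected), likewise treated ratios; the two groups are compared with
    a two-sided two-sample Student's t-test with pooled variance and
    ``df = n1 + n2 - 2``.

    Degenerate inputs: if both groups have zero variance and equal means the
    convention t = 0, NS applies; zero variance with unequal means is flagged
    ``degenerate`` with p absent.  Fewer than 2 ratios in either group is
    flagged ``insufficient`` with p absent and tier NS.
    """
    control: list[float] = []
    treated: list[float] = []
    for lv in levels:
        design = design_by_run[lv.run_id]
        for ch, r in lv.ratio_by_channel.items():
            if design.group_of[ch] is Group.CONTROL:
                control.append(r)
            else:
                treated.append(r)

    def _mean_sem(xs: list[float]) -> tuple[float, float]:
        if not xs:
            return float("nan"), float("nan")
        m = float(np.mean(xs))
        s = float(np.std(xs, ddof=1) / math.sqrt(len(xs))) if len(xs) > 1 else 0.0
        return m, s

    c_mean, c_sem = _mean_sem(control)
    t_mean, t_sem = _mean_sem(treated)

    if len(control) < 2 or len(treated) < 2:
        return DifferentialResult(
            peptide_key=levels[0].peptide_key if levels else ("", ""),
            gene=gene,
            control_mean=c_mean,
            control_sem=c_sem,
            n_control=len(control),
            treated_mean=t_mean,
            treated_sem=t_sem,
            n_treated=len(treated),
            p_value=None,
            tier=Tier.NS,
            fold_class=_fold_class(t_mean, fold_threshold) if treated else FoldClass.WITHIN,
            insufficient=True,
        )

    c_var = float(np.var(control, ddof=1))
    t_var = float(np.var(treated, ddof=1))
    degenerate = False
    if c_var == 0.0 and t_var == 0.0:
        if c_mean == t_mean:
            p: float | None = 1.0  # t = 0 convention
        else:
            p = None
            degenerate = True
    else:
        _, p_raw = stats.ttest_ind(treated, control, equal_var=True)
        p = float(p_raw)

    return DifferentialResult(
        peptide_key=levels[0].peptide_key,
        gene=gene,
        control_mean=c_mean,
        control_sem=c_sem,
        n_control=len(control),
        treated_mean=t_mean,
        treated_sem=t_sem,
        n_treated=len(treated),
        p_value=p,
        tier=_tier(p, tier_thresholds),
        fold_class=_fold_class(t_mean, fold_threshold),
        degenerate=degenerate,
    )


def differential_table(
    levels_by_peptide: Mapping[tuple[str, str], Sequence[RelativeLevelSet]],
    design_by_run: Mapping[str, ChannelDesign],
    gene_of: Mapping[tuple[str, str], str] | None = None,
    min_runs: int = 3,
    fold_threshold: float = 2.0,
) -> list[DifferentialResult]:
    """Differential results for every peptide detected in >= ``min_runs`` runs.

    Mirrors the published-table convention of tabulating only commonly
    detected peptides; peptides seen in fewer runs are excluded here but
    remain available in the per-run outputs.  A Benjamini-Hochberg adjusted
    p-value is attached to the returned list as ``result.bh_q`` for modern
    use, but tiers always derive from the raw p-values.
    """
    results = []
    for key, levels in sorted(levels_by_peptide.items()):
        runs = {lv.run_id for lv in levels}
        if len(runs) < min_runs:
            continue
        gene = gene_of.get(key, "") if gene_of else ""
        results.append(
            pool_and_test(
                levels, design_by_run, gene=gene, fold_threshold=fold_threshold
            )
        )
    ps = [r.p_value for r in results if r.p_value is not None]
    if ps:
        qs = iter(multipletests(ps, method="fdr_bh")[1])
        for r in results:
            object.__setattr__(r, "bh_q", next(qs) if r.p_value is not None else None)
    else:
        for r in results:
            object.__setattr__(r, "bh_q", None)
    return results


def rank_plot_data(ratios: Iterable[float]) -> list[tuple[int, float]]:
    """Ascending rank plot of per-replicate ratios (ties keep input order)."""
    vals = [r for r in ratios]
    for r in vals:
        if not math.isfinite(r):
            raise ValueError("ratios must be finite (drop ND before plotting)")
    ordered = sorted(vals)  # Timsort: stable, ties keep input order
    return [(i + 1, r) for i, r in enumerate(ordered)]


def fold_change_tally(
    ratios: Iterable[float], threshold: float = 2.0
) -> dict[str, float]:
    """Count ratios beyond a fold-change threshold (strict: <1/t or >t).

    Returns counts per class plus ``fraction_changed`` = (UP + DOWN) / total
    (0.0 on empty input).
    """
    counts = {FoldClass.UP_2X: 0, FoldClass.DOWN_2X: 0, FoldClass.WITHIN: 0}
    total = 0
    for r in ratios:
        counts[_fold_class(r, threshold)] += 1
        total += 1
    changed = counts[FoldClass.UP_2X] + counts[FoldClass.DOWN_2X]
    return {
        "UP_2X": counts[FoldClass.UP_2X],
        "DOWN_2X": counts[FoldClass.DOWN_2X],
        "WITHIN": counts[FoldClass.WITHIN],
        "total": total,
        "fraction_changed": changed / total if total else 0.0,
    }
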