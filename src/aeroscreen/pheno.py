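"""Follow-up phenotype models.

Growth-curve fitness uses the empirical (trapezoidal) area under the
OD(t) curve after subtracting the initial OD, normalized twice: to each
strain's vehicle-only curve and to the non-targeting control strain.
Combination effects are predicted by the multiplicative model of
genetic/chemical interaction, f_pred = f1 * f2; a measured fitness
below the prediction indicates synergy/sensitization. Spot-dilution
plating is scored as visible-dilution differences versus the control,
and mutation frequency as rifampicin-resistant CFU per cell plated with
a two-tailed two-sample t-test (Welch by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class GrowthCurve:
    strain_id: str
    time: np.ndarray  # hours, strictly increasing
    od: np.ndarray
    treatment: str = "vehicle"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time.size != self.od.size:
            raise ValueError("time and od must have equal length")
        if self.time.size < 2:
            raise ValueError("a growth curve needs at least 2 time points")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time points must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("OD readings must be non-negative")


def auc_empirical(curve: GrowthCurve) -> float:
    """Trapezoidal area under OD(t) after baseline (initial-OD) subtraction.

    The baseline convention removes lag-phase offsets; negative excursions
    below the initial OD are floored at zero.
    """
    y = np.maximum(curve.od - curve.od[0], 0.0)
    return float(np.trapezoid(y, curve.time))


def relative_fitness(
    test: GrowthCurve,
    vehicle: GrowthCurve,
    control_treated: GrowthCurve,
    control_vehicle: GrowthCurve,
) -> float:
    """Doubly normalized fitness:
    [auc(test)/auc(vehicle)] / [auc(control treated)/auc(control vehicle)].
    """
    av, acv = auc_empirical(vehicle), auc_empirical(control_vehicle)
    if av <= 0 or acv <= 0:
        raise ValueError("vehicle curves must have positive AUC")
    act = auc_empirical(control_treated)
    if act <= 0:
        raise ValueError("control treated curve must have positive AUC")
    return (auc_empirical(test) / av) / (act / acv)


def predicted_combined_fitness(f_knockdown: float, f_treatment: float) -> float:
    """Multiplicative-model prediction for a knockdown x treatment combination."""
    if f_knockdown < 0 or f_treatment < 0:
        raise ValueError("fitness values must be non-negative")
    return f_knockdown * f_treatment


def interaction(measured: float, f_knockdown: float, f_treatment: float) -> dict:
    """Measured-vs-predicted combination fitness; negative difference = synergy."""
    pred = predicted_combined_fitness(f_knockdown, f_treatment)
    return dict(
        predicted=pred,
        measured=measured,
        difference=measured - pred,
        ratio=measured / pred if pred > 0 else np.nan,
    )


def spot_score(
    strain_visible,
    control_visible,
    size_calls=None,
) -> dict:
    """Spot-dilution fitness score and colony-size call.

    Per scorer/replicate the score is (strain visible spots) - (control
    visible spots); a knockdown visible through 5 dilutions against a
    control visible through 6 scores -1. The reported score is the
    median across scorers and the size call the most prevalent category.
    """
    strain = np.atleast_1d(np.asarray(strain_visible, dtype=float))
    control = np.atleast_1d(np.asarray(control_visible, dtype=float))
    if strain.size == 0 or control.size == 0:
        raise ValueError("need at least one scorer")
    if strain.size != control.size:
        raise ValueError("strain and control dilution series lengths must match")
    scores = strain - control
    out = dict(scores=scores.tolist(), fitness_score=float(np.median(scores)))
    if size_calls is not None:
        vals, counts = np.unique(np.asarray(size_calls), return_counts=True)
        out["size_call"] = str(vals[np.argmax(counts)])
    return out


def mutation_frequency(
    test_rif_cfu,
    test_cells_plated: float,
    control_rif_cfu,
    control_cells_plated: float,
    equal_var: bool = False,
) -> dict:
    """Mutation frequencies, fold change, and two-tailed t-test.

    Per-replicate frequency = resistant CFU / cells plated. Welch's
    unequal-variance t-test by default (``equal_var=True`` for the
    pooled-variance Student variant). Degenerate inputs (zero variance
    in both groups, or a zero control mean) are flagged rather than
    erroring.
    """
    test = np.asarray(test_rif_cfu, dtype=float) / float(test_cells_plated)
    control = np.asarray(control_rif_cfu, dtype=float) / float(control_cells_plated)
    if test.size < 2:
        raise ValueError("need >= 2 test replicates")
    out = dict(
        test_frequencies=test.tolist(),
        control_frequencies=control.tolist(),
        test_mean=float(test.mean()),
        control_mean=float(control.mean()),
        flags=[],
    )
    if control.mean() == 0:
        out["fold_change"] = np.nan
        out["flags"].append("zero_control_frequency")
    else:
        out["fold_change"] = float(test.mean() / control.mean())
    if test.std(ddof=0) == 0 and control.std(ddof=0) == 0:
        out["p"] = 1.0
        out["flags"].append("zero_variance")
    else:
        out["p"] = float(stats.ttest_ind(test, control, equal_var=equal_var).pvalue)
    return out
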