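"""Dose-matrix combination-screen analytics.

A screen is a grid of dose pairs (drug A x drug B) with replicate raw
luminescence readings and vehicle-only control wells. Raw light units are
normalized to the control mean to give percent viability; percent
inhibition is 100 - viability. The additive expectation at a dose pair is
the sum of the two single-agent inhibitions at the marginal doses, capped
at 100% by default (an uncapped sum exceeds total kill at high doses; pass
``cap=None`` for the plain sum). The delta is observed minus expected:
positive deltas indicate cooperation beyond additivity, negative deltas
antagonism. Inhibition below zero (growth stimulation) is retained, not
floored — antagonism detection needs it.

Per-dose-pair testing compares replicate observed inhibitions against
replicate-matched expected values (the capped sum of the same replicate's
monotherapy inhibitions) with a Welch t-test (or a paired t-test), and
corrects across all dose pairs of the screen with Benjamini-Hochberg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PLATE_COLUMNS = ("drugA_dose", "drugB_dose", "replicate", "raw")


@dataclass
class PlateMeasurements:
    """Long-format raw plate readings plus vehicle-control wells.

    ``wells`` has columns drugA_dose, drugB_dose, replicate, raw; controls
    are either listed in ``controls`` (raw light units) or flagged with an
    ``is_control`` column in ``wells``. If neither is present, the (0, 0)
    dose-pair wells double as controls.
    """

    wells: pd.DataFrame
    controls: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing = [c for c in PLATE_COLUMNS if c not in self.wells.columns]
        if missing:
            raise ValueError(f"plate table missing columns {missing}")
        if (self.wells["raw"] < 0).any():
            raise ValueError("raw light units must be >= 0")
        if "is_control" in self.wells.columns:
            mask = self.wells["is_control"].astype(bool)
            self.controls = self.wells.loc[mask, "raw"].to_numpy(float)
            self.wells = self.wells.loc[~mask].reset_index(drop=True)
        elif self.controls is None:
            zero = (self.wells["drugA_dose"] == 0) & (self.wells["drugB_dose"] == 0)
            self.controls = self.wells.loc[zero, "raw"].to_numpy(float)
        else:
            self.controls = np.asarray(self.controls, dtype=float)
        if self.controls.size == 0:
            raise ValueError("no control wells found")

    @classmethod
    def read_tsv(cls, path) -> "PlateMeasurements":
        return cls(pd.read_csv(path, sep="\t"))


def normalize_viability(plate: PlateMeasurements) -> pd.DataFrame:
    """Normalize raw light units to the plate control mean.

    Returns the inhibition surface: one row per well with ``viability`` =
    100 * raw / mean(controls) and ``inhibition`` = 100 - viability.
    Requires a positive control mean and a complete dose grid (every
    drugA dose crossed with every drugB dose).
    """
    cmean = float(np.mean(plate.controls))
    if cmean <= 0:
        raise ValueError(f"control mean must be positive, got {cmean}")
    surface = plate.wells.copy()
    surface["viability"] = 100.0 * surface["raw"] / cmean
    surface["inhibition"] = 100.0 - surface["viability"]
    doses_a = sorted(surface["drugA_dose"].unique())
    doses_b = sorted(surface["drugB_dose"].unique())
    present = set(zip(surface["drugA_dose"], surface["drugB_dose"]))
    for da in doses_a:
        for db in doses_b:
            if (da, db) not in present:
                raise ValueError(f"missing dose pair ({da}, {db}) in plate")
    return surface


def expected_additive(
    inhibition_a: float, inhibition_b: float, cap: float | None = 100.0
):
    """Additive expectation: single-agent inhibitions summed, capped.

    Works elementwise on arrays. ``cap=None`` disables capping (plain sum).
    Negative inputs (stimulation) pass through the sum.
    """
    total = np.asarray(inhibition_a, dtype=float) + np.asarray(
        inhibition_b, dtype=float
    )
    if cap is not None:
        total = np.minimum(total, cap)
    if total.ndim == 0:
        return float(total)
    return total


def _margins(surface: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monotherapy wells: (drug A alone, drug B alone), replicate level."""
    a = surface[(surface["drugB_dose"] == 0) & (surface["drugA_dose"] > 0)]
    b = surface[(surface["drugA_dose"] == 0) & (surface["drugB_dose"] > 0)]
    return a, b


def combo_delta(surface: pd.DataFrame, cap: float | None = 100.0) -> pd.DataFrame:
    """Delta = mean observed combination inhibition - additive expectation.

    One row per combination dose pair (both doses > 0), with the expected
    inhibition built from the monotherapy margin means at the pair's doses.
    """
    mono_a, mono_b = _margins(surface)
    mean_a = mono_a.groupby("drugA_dose")["inhibition"].mean()
    mean_b = mono_b.groupby("drugB_dose")["inhibition"].mean()
    combos = surface[(surface["drugA_dose"] > 0) & (surface["drugB_dose"] > 0)]
    rows = []
    for (da, db), grp in combos.groupby(["drugA_dose", "drugB_dose"]):
        if da not in mean_a.index:
            raise ValueError(f"missing monotherapy margin for drug A dose {da}")
        if db not in mean_b.index:
            raise ValueError(f"missing monotherapy margin for drug B dose {db}")
        expected = expected_additive(mean_a[da], mean_b[db], cap)
        observed = float(grp["inhibition"].mean())
        rows.append(
            {
                "drugA_dose": da,
                "drugB_dose": db,
                "expected": expected,
                "observed": observed,
                "delta": observed - expected,
            }
        )
    return pd.DataFrame(rows)


def combo_test(
    surface: pd.DataFrame,
    cap: float | None = 100.0,
    paired: bool = False,
    mt_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Per-dose-pair test of observed vs replicate-matched expected inhibition.

    Each expected replicate is the capped sum of the same replicate's two
    monotherapy inhibitions. The default test is Welch's two-sample t;
    ``paired=True`` uses a paired t-test on the replicate-matched
    differences. P-values are corrected across all dose pairs of the
    screen (``mt_method`` passed to statsmodels ``multipletests``).

    Returns the :func:`combo_delta` table extended with ``p``, ``p_adj``
    and ``mlog10_p_adj``.
    """
    mono_a, mono_b = _margins(surface)
    if mono_a.empty or mono_b.empty:
        raise ValueError("monotherapy margins missing from surface")
    rep_a = mono_a.set_index(["drugA_dose", "replicate"])["inhibition"]
    rep_b = mono_b.set_index(["drugB_dose", "replicate"])["inhibition"]
    combos = surface[(surface["drugA_dose"] > 0) & (surface["drugB_dose"] > 0)]
    rows = []
    for (da, db), grp in combos.groupby(["drugA_dose", "drugB_dose"]):
        if len(grp) < 2:
            raise ValueError(f"dose pair ({da}, {db}) has <2 replicates")
        observed = grp.set_index("replicate")["inhibition"]
        try:
            exp_reps = pd.Series(
                {
                    r: expected_additive(rep_a[(da, r)], rep_b[(db, r)], cap)
                    for r in observed.index
                }
            )
        except KeyError as exc:
            raise ValueError(
                f"missing monotherapy replicate for dose pair ({da}, {db})"
            ) from exc
        obs = observed.to_numpy(float)
        exp = exp_reps.reindex(observed.index).to_numpy(float)
        if np.allclose(obs.var(), 0) and np.allclose(exp.var(), 0):
            p = 1.0 if math.isclose(obs.mean(), exp.mean()) else 0.0
        elif paired:
            p = float(stats.ttest_rel(obs, exp).pvalue)
        else:
            p = float(stats.ttest_ind(obs, exp, equal_var=False).pvalue)
        rows.append(
            {
                "drugA_dose": da,
                "drugB_dose": db,
                "expected": float(exp.mean()),
                "observed": float(obs.mean()),
                "delta": float(obs.mean() - exp.mean()),
                "p": p,
            }
        )
    result = pd.DataFrame(rows)
    result["p_adj"] = multipletests(result["p"], method=mt_method)[1]
    result["mlog10_p_adj"] = -np.log10(result["p_adj"].clip(lower=1e-320))
    return result


def contour_table(surface: pd.DataFrame) -> pd.DataFrame:
    """Long-format (x = doseA, y = doseB, z = mean viability) for contours."""
    out = (
        surface.groupby(["drugA_dose", "drugB_dose"])["viability"]
        .mean()
        .reset_index()
        .rename(columns={"drugA_dose": "x", "drugB_dose": "y", "viability": "z"})
    )
    return out
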