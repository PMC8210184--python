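"""Quantifying prey response to hub-bait expression modulation.

For each prey the screen yields replicate MS2 intensities in four arms: an
overexpression-modulated line and a knockdown-modulated line, each paired
with an empty-backbone control.  This module normalizes samples, averages
replicate runs, forms log2 fold-changes of the averaged intensities
(modulated over matching control, per line), tests the modulation effect
with a two-way fixed-effects ANOVA on log intensities (cell line x
genotype), and classifies each prey as *concordant* (up under
overexpression AND down under knockdown — evidence of stoichiometric
coupling to the hub), *discordant* (both fold-changes on the same side) or
*unchanged*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyDesignError
from .filtering import IntensityMatrix

NORMALIZE_METHODS = ("none", "total", "median")
MISSING_POLICIES = ("impute_floor", "ignore_missing")
CONCORDANCE_CLASSES = ("concordant", "discordant", "unchanged")


def normalize_samples(matrix: IntensityMatrix, method: str = "median") -> IntensityMatrix:
    """Rescale each sample so its chosen intensity statistic is equal across samples.

    ``method`` is one of ``none`` (identity), ``total`` (equal sums of
    non-missing intensities) or ``median`` (equal medians).  The common
    target is the mean of the per-sample statistics, so the overall
    intensity scale is preserved.  Missingness is untouched.
    """
    if method not in NORMALIZE_METHODS:
        raise ValueError(f"method must be one of {NORMALIZE_METHODS}, got {method!r}")
    if method == "none":
        return matrix
    stat = matrix.values.sum(skipna=True) if method == "total" else matrix.values.median(skipna=True)
    if (matrix.values.notna().sum() == 0).any():
        empty = matrix.values.columns[matrix.values.notna().sum() == 0][0]
        raise EmptyDesignError(f"sample {empty!r} has no non-missing values")
    if (stat <= 0).any():
        bad = stat.index[stat <= 0][0]
        raise ValueError(f"sample {bad!r} has non-positive {method} statistic")
    factors = stat.mean() / stat
    return IntensityMatrix(values=matrix.values * factors, samples=matrix.samples.copy())


def aggregate_replicates(
    matrix: IntensityMatrix,
    bait: str,
    cell_line: str,
    condition: str,
    missing_policy: str = "impute_floor",
    floor: float = 1.0,
) -> pd.Series:
    """Arithmetic mean intensity over replicate runs, per protein.

    Under ``impute_floor`` a run in which the protein was not detected
    contributes the floor value (the detection limit) to the mean; under
    ``ignore_missing`` only detected runs are averaged.  Proteins missing in
    every run aggregate to NaN either way.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(
            f"missing_policy must be one of {MISSING_POLICIES}, got {missing_policy!r}"
        )
    cols = matrix.run_ids(bait=bait, cell_line=cell_line, condition=condition, is_mock=False)
    if not cols:
        raise EmptyDesignError(
            f"no runs for bait={bait!r}, cell_line={cell_line!r}, condition={condition!r}"
        )
    sub = matrix.values[cols]
    detected_any = sub.notna().any(axis=1)
    if missing_policy == "impute_floor":
        agg = sub.fillna(floor).mean(axis=1)
    else:
        agg = sub.mean(axis=1)
    agg[~detected_any] = np.nan
    agg.name = f"{bait}|{cell_line}|{condition}"
    return agg


def compute_log2fc(mean_mod, mean_ctrl, pseudo: float = 1.0):
    """log2((mean_mod + pseudo) / (mean_ctrl + pseudo)); scalar or vectorized.

    The pseudocount keeps fold-changes finite when one side is near zero;
    with raw MS2 intensities in the 1e5-1e7 range the default of one
    intensity unit is negligible.  Missing means propagate to NaN.
    """
    if pseudo < 0:
        raise ValueError(f"pseudo must be >= 0, got {pseudo}")
    mod = np.asarray(mean_mod, dtype=float)
    ctrl = np.asarray(mean_ctrl, dtype=float)
    if np.nanmin(mod, initial=0.0) < 0 or np.nanmin(ctrl, initial=0.0) < 0:
        raise ValueError("negative mean intensity")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(mod + pseudo) - np.log2(ctrl + pseudo)
    if np.isscalar(mean_mod) and np.isscalar(mean_ctrl):
        return float(out)
    return out


@dataclass(frozen=True)
class ModulationTest:
    """Outcome of the two-way ANOVA genotype test for one protein."""

    p_value: float
    f_stat: float
    df_num: int
    df_den: int
    defined: bool
    reason: str = ""


def _dummies(codes: np.ndarray) -> np.ndarray:
    levels = sorted(set(codes.tolist()))
    return np.column_stack([(codes == lv).astype(float) for lv in levels[1:]])


def anova_genotype_p(y, line, genotype) -> ModulationTest:
    """Type-II F test of the genotype main effect in a two-way layout.

    Fits ``y ~ line * genotype`` by least squares and compares the sum of
    squares explained by genotype after the line effect against the
    residual of the full interaction model — the conventional two-way
    fixed-effects ANOVA main effect, computed directly for speed at
    simulation scale.  Zero residual variance yields an explicitly
    undefined result rather than a silent 0 or 1.
    """
    y = np.asarray(y, dtype=float)
    line = np.asarray(line)
    genotype = np.asarray(genotype)
    n = len(y)
    if not (len(line) == len(genotype) == n):
        raise ValueError("y, line and genotype must have equal length")
    if len(set(genotype.tolist())) < 2 or len(set(line.tolist())) < 2:
        raise EmptyDesignError("need >= 2 levels of both line and genotype")

    d_line = _dummies(line)
    d_geno = _dummies(genotype)
    inter = np.column_stack(
        [d_line[:, i] * d_geno[:, j] for i in range(d_line.shape[1]) for j in range(d_geno.shape[1])]
    )
    one = np.ones((n, 1))
    x_line = np.hstack([one, d_line])
    x_lg = np.hstack([one, d_line, d_geno])
    x_full = np.hstack([one, d_line, d_geno, inter])

    def rss(x):
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        r = y - x @ beta
        return float(r @ r)

    rss_line, rss_lg, rss_full = rss(x_line), rss(x_lg), rss(x_full)
    df_num = d_geno.shape[1]
    df_den = n - int(np.linalg.matrix_rank(x_full))
    scale = max(1.0, float(y @ y))
    if df_den <= 0:
        return ModulationTest(np.nan, np.nan, df_num, df_den, False, "no residual df")
    if rss_full <= 1e-12 * scale:
        return ModulationTest(np.nan, np.nan, df_num, df_den, False, "zero residual variance")
    f = ((rss_line - rss_lg) / df_num) / (rss_full / df_den)
    p = float(stats.f.sf(f, df_num, df_den))
    return ModulationTest(p, float(f), df_num, df_den, True)


def test_modulation(
    matrix: IntensityMatrix,
    protein: str,
    bait: str,
    missing_policy: str = "impute_floor",
    floor: float = 1.0,
) -> ModulationTest:
    """Two-way ANOVA (cell line x genotype) on log intensities of one prey.

    Uses every non-mock replicate run of the given bait across both lines
    and both genotype conditions.  Intensities are log-transformed first
    (multiplicative noise model); non-detected runs are imputed at the floor
    under the default policy and dropped under ``ignore_missing``.
    """
    cols = matrix.run_ids(bait=bait, is_mock=False)
    if not cols:
        raise EmptyDesignError(f"no runs for bait={bait!r}")
    sub = matrix.values.loc[protein, cols]
    meta = matrix.samples.loc[cols]
    vals = sub.to_numpy(dtype=float)
    if missing_policy == "impute_floor":
        vals = np.where(np.isnan(vals), floor, vals)
        keep = np.ones(len(vals), dtype=bool)
    else:
        keep = ~np.isnan(vals)
    if keep.sum() == 0:
        return ModulationTest(np.nan, np.nan, 0, 0, False, "no detected runs")
    y = np.log(vals[keep])
    return anova_genotype_p(
        y, meta["cell_line"].to_numpy()[keep], meta["condition"].to_numpy()[keep]
    )


def classify_concordance(
    log2fc_up: float,
    log2fc_down: float,
    p_value: float = np.nan,
    fc_min: float = 0.0,
    alpha: float | None = None,
) -> str:
    """Concordance class from the pair of per-line log2 fold-changes.

    *concordant*: up-line fold-change above ``fc_min`` AND down-line below
    ``-fc_min`` (optionally also ``p < alpha``); *discordant*: both beyond
    ``fc_min`` on the same side; anything else, including missing
    fold-changes and exact ties at ``fc_min``, is *unchanged*.
    """
    if fc_min < 0:
        raise ValueError(f"fc_min must be >= 0, got {fc_min}")
    if log2fc_up is None or log2fc_down is None:
        return "unchanged"
    up, down = float(log2fc_up), float(log2fc_down)
    if np.isnan(up) or np.isnan(down):
        return "unchanged"
    if up > fc_min and down < -fc_min:
        if alpha is not None and not (np.isfinite(p_value) and p_value < alpha):
            return "unchanged"
        return "concordant"
    if (up > fc_min and down > fc_min) or (up < -fc_min and down < -fc_min):
        return "discordant"
    return "unchanged"


def quantify_modulation(
    matrix: IntensityMatrix,
    proteins,
    bait: str,
    up_line: str,
    down_line: str,
    normalize: str = "none",
    pseudo: float = 1.0,
    fc_min: float = 0.0,
    alpha: float | None = None,
    missing_policy: str = "impute_floor",
    floor: float = 1.0,
    control_condition: str = "control",
    modulated_condition: str = "modulated",
    run_tests: bool = True,
) -> pd.DataFrame:
    """Per-protein modulation table for one bait's interactors.

    Columns: ``log2fc_up`` (overexpression line, modulated vs control),
    ``log2fc_down`` (knockdown line, modulated vs control), ``p_value``
    (genotype effect, NaN when undefined) and ``concordance``.
    """
    matrix = normalize_samples(matrix, normalize)
    proteins = sorted(proteins)

    def agg(line, cond):
        return aggregate_replicates(
            matrix, bait, line, cond, missing_policy=missing_policy, floor=floor
        ).reindex(proteins)

    fc_up = compute_log2fc(
        agg(up_line, modulated_condition), agg(up_line, control_condition), pseudo
    )
    fc_down = compute_log2fc(
        agg(down_line, modulated_condition), agg(down_line, control_condition), pseudo
    )
    if run_tests:
        pvals = np.array(
            [
                test_modulation(matrix, p, bait, missing_policy, floor).p_value
                for p in proteins
            ]
        )
    else:
        pvals = np.full(len(proteins), np.nan)
    classes = [
        classify_concordance(u, d, p, fc_min=fc_min, alpha=alpha)
        for u, d, p in zip(fc_up, fc_down, pvals)
    ]
    return pd.DataFrame(
        {
            "log2fc_up": np.asarray(fc_up, dtype=float),
            "log2fc_down": np.asarray(fc_down, dtype=float),
            "p_value": pvals,
            "concordance": classes,
        },
        index=pd.Index(proteins, name="protein_id"),
    )
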