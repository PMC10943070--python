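"""Bayesian bait-prey interaction scoring against condition-matched controls.

Each (bait, condition) group is scored against the same-condition
ligase-only control samples.  The model is a two-component equal-variance
mixture on log2 intensities: for a prey with control mean ``mu0`` and pooled
within-group standard deviation ``s``, a bait replicate value ``x`` has
density ``f0`` centred at ``mu0`` under "no interaction" and ``f1`` centred
at ``mu0 + delta`` under "true interaction", with a fixed minimal enrichment
offset ``delta``.  The per-replicate posterior is

    P(true | x) = prior * f1(x) / (prior * f1(x) + (1 - prior) * f0(x))

Because ``mu0`` and ``s`` are estimated from a handful of replicates, the
component densities are Student-t predictive densities (scale inflated for
the control-mean uncertainty, degrees of freedom = pooled residual df)
rather than plug-in normals; with known variance they reduce to the normal
mixture.  The t likelihood ratio is clamped at its analytic maximum so the
posterior is monotone in enrichment.  ``mu0`` is the mean of the prey's
*observed* control values; only when the prey is absent from every control
is it imputed at the control floor (a low quantile of all observed control
intensities) — an unobserved control background is read as below detection.

Missing bait replicates count as posterior 0 (absence is evidence of
absence), and AvgP averages the posteriors over *all* bait replicates.  The
Bayesian false discovery rate at rank k (preys ranked by decreasing AvgP
within a group) is the running mean of (1 - AvgP) — the standard SAINT BFDR
construction; the significance rule is BFDR <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import t as t_dist

from .errors import ConfigurationError, DesignError
from .quant_io import IntensityMatrix, SampleDesign

#: columns of the scored-interaction exchange table
SCORE_COLUMNS = ("bait", "condition", "prey", "avg_p", "bfdr", "log2fc", "significant")

ND = "N.D."  # not-detected marker used in text exports


@dataclass
class ScoringParams:
    """Knobs of the scoring model.

    enrichment_delta
        Minimal log2 shift regarded as a true interaction (mixture offset).
    prior_true
        Prior probability that a (bait, prey) pair interacts.
    control_floor_quantile
        Quantile of all observed control values used to impute missing
        control background (left-censored detection floor).
    variance_floor
        Lower bound on the pooled within-group standard deviation (log2),
        preventing degenerate certainty from near-identical replicates.
    """

    enrichment_delta: float = 2.0
    prior_true: float = 0.5
    control_floor_quantile: float = 0.05
    min_bait_replicates_present: int = 1
    bfdr_threshold: float = 0.05
    variance_floor: float = 0.25

    def validate(self) -> None:
        if self.enrichment_delta <= 0:
            raise ConfigurationError("enrichment_delta must be > 0")
        if not 0.0 < self.prior_true < 1.0:
            raise ConfigurationError("prior_true must be in (0, 1)")
        if not 0.0 < self.control_floor_quantile <= 0.5:
            raise ConfigurationError("control_floor_quantile must be in (0, 0.5]")
        if not 0.0 < self.bfdr_threshold < 1.0:
            raise ConfigurationError("bfdr_threshold must be in (0, 1)")
        if self.min_bait_replicates_present < 1:
            raise ConfigurationError("min_bait_replicates_present must be >= 1")


def _groups(m: IntensityMatrix, design: SampleDesign, bait: str, condition: str):
    bait_cols = design.bait_samples(bait, condition)
    ctrl_cols = design.control_samples(condition)
    if not bait_cols:
        raise DesignError(f"no samples for bait {bait!r} in condition {condition!r}")
    if len(ctrl_cols) < 2:
        raise DesignError(
            f"need >= 2 control samples for condition {condition!r}, found {len(ctrl_cols)}"
        )
    missing = [c for c in bait_cols + ctrl_cols if c not in m.values.columns]
    if missing:
        raise DesignError(f"design samples absent from matrix: {missing}")
    return bait_cols, ctrl_cols


def control_floor(m: IntensityMatrix, design: SampleDesign, condition: str, quantile: float) -> float:
    """Imputation value for missing control background: a low quantile of all
    observed control intensities in that condition."""
    ctrl_cols = design.control_samples(condition)
    vals = m.values[ctrl_cols].to_numpy().ravel()
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise DesignError(f"no observed control values in condition {condition!r}")
    return float(np.quantile(vals, quantile))


def _posteriors(
    X: np.ndarray,
    mu0: np.ndarray,
    s: np.ndarray,
    df: np.ndarray,
    n_ctrl: np.ndarray,
    params: ScoringParams,
) -> np.ndarray:
    """Per-replicate posteriors from the two-component t predictive mixture.

    The predictive scale inflates the pooled sd for the uncertainty of the
    estimated control mean; the log likelihood ratio is clamped at its
    analytic maximum (reached at z = (a + sqrt(a^2 + 4 df)) / 2 standardized
    units, a = delta/scale) so the posterior never decreases with enrichment.
    """
    scale = s * np.sqrt(1.0 + 1.0 / np.maximum(n_ctrl, 1))
    a = params.enrichment_delta / scale  # standardized enrichment offset
    z = (X - mu0[:, None]) / scale[:, None]
    z_peak = (a + np.sqrt(a**2 + 4.0 * df)) / 2.0
    z = np.minimum(z, z_peak[:, None])
    dfc = df[:, None]
    llr = t_dist.logpdf(z - a[:, None], dfc) - t_dist.logpdf(z, dfc)
    return expit(llr + logit(params.prior_true))


def score_group(
    m: IntensityMatrix,
    design: SampleDesign,
    bait: str,
    condition: str,
    params: ScoringParams | None = None,
) -> pd.DataFrame:
    """Score every prey observed in the bait group against the condition control.

    Returns one row per prey with at least ``min_bait_replicates_present``
    present bait values: columns ``bait, condition, prey, avg_p, log2fc`` plus
    ``posteriors`` (tuple, one entry per bait replicate).  BFDR is assigned
    separately by :func:`compute_bfdr`.
    """
    params = params or ScoringParams()
    params.validate()
    bait_cols, ctrl_cols = _groups(m, design, bait, condition)
    floor = control_floor(m, design, condition, params.control_floor_quantile)

    X = m.values[bait_cols].to_numpy(dtype=float)  # (n_prey, r_bait)
    C = m.values[ctrl_cols].to_numpy(dtype=float)  # (n_prey, r_ctrl)
    ctrl_present = ~np.isnan(C)
    n_ctrl = ctrl_present.sum(axis=1)
    ctrl_sum = np.nansum(np.where(ctrl_present, C, 0.0), axis=1)
    mu0 = np.where(n_ctrl > 0, ctrl_sum / np.maximum(n_ctrl, 1), floor)

    present = ~np.isnan(X)
    n_present = present.sum(axis=1)

    # pooled within-group sd per prey (bait and observed-control deviations)
    bait_mean = np.where(
        n_present > 0,
        np.nansum(np.where(present, X, 0.0), axis=1) / np.maximum(n_present, 1),
        0.0,
    )
    ss_bait = np.nansum(np.where(present, (X - bait_mean[:, None]) ** 2, 0.0), axis=1)
    ss_ctrl = np.nansum(np.where(ctrl_present, (C - mu0[:, None]) ** 2, 0.0), axis=1)
    df = np.maximum(n_present - 1, 0) + np.maximum(n_ctrl - 1, 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled_sd = np.sqrt((ss_bait + ss_ctrl) / np.maximum(df, 1))
    s = np.maximum(np.where(df >= 1, pooled_sd, 0.0), params.variance_floor)

    post = _posteriors(X, mu0, s, np.maximum(df, 1), n_ctrl, params)
    post = np.where(present, post, 0.0)
    avg_p = post.sum(axis=1) / X.shape[1]

    log2fc = np.where(
        n_present > 0,
        np.nansum(np.where(present, X, 0.0), axis=1) / np.maximum(n_present, 1) - mu0,
        np.nan,
    )

    keep = n_present >= params.min_bait_replicates_present
    preys = np.asarray(m.proteins, dtype=object)
    out = pd.DataFrame(
        {
            "bait": bait,
            "condition": condition,
            "prey": preys[keep],
            "avg_p": avg_p[keep],
            "log2fc": log2fc[keep],
            "posteriors": [tuple(row) for row in post[keep]],
        }
    )
    return out


def compute_bfdr(scores: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Ranked Bayesian FDR within each (bait, condition) group.

    Preys are ranked by AvgP descending (prey ID breaks ties for
    determinism); BFDR at rank k is the running mean of (1 - AvgP); tied AvgP
    values all receive the largest BFDR in their tie block.  Adds ``bfdr``
    and ``significant`` columns.
    """
    if scores.empty:
        out = scores.copy()
        out["bfdr"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out

    pieces = []
    for _, grp in scores.groupby(["bait", "condition"], sort=False):
        grp = grp.sort_values(
            ["avg_p", "prey"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        one_minus = 1.0 - grp["avg_p"].to_numpy()
        bfdr = np.cumsum(one_minus) / np.arange(1, len(grp) + 1)
        # tie blocks share their worst (largest) BFDR
        grp["bfdr"] = bfdr
        grp["bfdr"] = grp.groupby("avg_p", sort=False)["bfdr"].transform("max")
        pieces.append(grp)
    out = pd.concat(pieces, ignore_index=True)
    out["significant"] = out["bfdr"] <= threshold
    return out


def log2_enrichment(
    m: IntensityMatrix,
    design: SampleDesign,
    bait: str,
    condition: str,
    params: ScoringParams | None = None,
) -> pd.Series:
    """Per-prey log2 fold change over the condition control, for every matrix row.

    NaN marks preys not detected in any bait replicate (exported as "N.D.").
    The control mean uses observed control values; a prey absent from every
    control is imputed at the control floor.
    """
    params = params or ScoringParams()
    bait_cols, ctrl_cols = _groups(m, design, bait, condition)
    floor = control_floor(m, design, condition, params.control_floor_quantile)
    X = m.values[bait_cols].to_numpy(dtype=float)
    C = m.values[ctrl_cols].to_numpy(dtype=float)
    ctrl_present = ~np.isnan(C)
    n_ctrl = ctrl_present.sum(axis=1)
    mu0 = np.where(
        n_ctrl > 0,
        np.nansum(np.where(ctrl_present, C, 0.0), axis=1) / np.maximum(n_ctrl, 1),
        floor,
    )
    present = ~np.isnan(X)
    n_present = present.sum(axis=1)
    fc = np.nansum(np.where(present, X, 0.0), axis=1) / np.maximum(n_present, 1) - mu0
    fc = np.where(n_present > 0, fc, np.nan)
    return pd.Series(fc, index=m.values.index, name="log2fc")


def score_experiment(
    m: IntensityMatrix,
    design: SampleDesign,
    params: ScoringParams | None = None,
) -> pd.DataFrame:
    """Score all bait x condition groups and assign BFDR; the pipeline's
    central scored-interaction table."""
    params = params or ScoringParams()
    pieces = [
        score_group(m, design, bait, condition, params)
        for bait in design.baits
        for condition in design.conditions
    ]
    scored = pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame()
    return compute_bfdr(scored, params.bfdr_threshold)


def write_scores(scores: pd.DataFrame, path) -> None:
    """Write the scored-interaction table (tab-delimited, N.D. for missing fold change)."""
    out = scores[list(SCORE_COLUMNS)].copy()
    out["log2fc"] = out["log2fc"].map(lambda v: ND if pd.isna(v) else f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False)


def read_scores(path, threshold: float = 0.05) -> pd.DataFrame:
    """Read a scored-interaction table, including pre-scored tables exported
    from external scoring software (requires bait, condition, prey, bfdr)."""
    df = pd.read_csv(path, sep="\t")
    required = {"bait", "condition", "prey", "bfdr"}
    missing = required - set(df.columns)
    if missing:
        raise DesignError(f"scores table missing columns: {sorted(missing)}")
    if "log2fc" in df.columns:
        df["log2fc"] = pd.to_numeric(
            df["log2fc"].replace(ND, np.nan), errors="coerce"
        )
    else:
        df["log2fc"] = np.nan
    if "avg_p" not in df.columns:
        df["avg_p"] = np.nan
    df["significant"] = df["bfdr"] <= threshold
    return df
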