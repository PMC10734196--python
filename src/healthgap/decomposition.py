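"""Threefold Blinder-Oaxaca decomposition of a two-group prevalence gap.

The gap D = ybar_1 - ybar_2 between group 1 (urban analogue) and group 2
(rural analogue) is split into

    endowment   E — differences in covariate levels,
    coefficient C — differences in the returns to those levels
                    (including the intercept / "unobservables" share B),
    interaction I — the simultaneous presence of both.

Two modes are provided. ``linear`` fits group-specific weighted
linear-probability models and applies the summation formulas

    E = sum_j b2_j (x1bar_j - x2bar_j)
    C = sum_j x2bar_j (b1_j - b2_j) + (b1_0 - b2_0)
    I = sum_j (x1bar_j - x2bar_j)(b1_j - b2_j)

(the default "from the group-2 viewpoint": E weighted by group-2
coefficients, C evaluated at group-2 means). ``logit_counterfactual`` fits
group-specific weighted logits and contrasts weighted mean predicted
probabilities under counterfactual (covariates, coefficients) pairings, with
I defined residually so E + C + I = D holds by construction. Detailed
per-covariate-level contributions use the linear algebra (rescaled to the
logit aggregates in counterfactual mode), and confidence intervals come from
a stratified nonparametric bootstrap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_model import AnalysisDataset, CovariateSchema, DataError, encode_design_matrix
from .logit import LogitFit, RankDeficiencyError, fit_logit_irls

COMPONENTS = ("D", "E", "C", "I", "B")


class UnstableResamplingError(DataError):
    """More than 20% of bootstrap replicates failed to fit."""


@dataclass
class DetailedContribution:
    """Per-covariate-level split of the aggregate E and C components.

    ``table`` has one row per level (reference rows included for layout) with
    E_part / C_part and their percent-of-D shares; the intercept difference
    appears as the ``constant`` C row. In linear mode parts sum to the
    aggregates exactly; in counterfactual mode they are the linear parts
    rescaled by one global factor per component so the sums match.
    """

    table: pd.DataFrame
    constant_C: float
    constant_pct: float | None
    normalization: str
    mode: str


@dataclass
class DecompositionResult:
    """Aggregate threefold decomposition of the group prevalence gap."""

    mean_pred_group1: float
    mean_pred_group2: float
    D: float
    E: float
    C: float
    I: float
    B: float
    pct_E: float | None
    pct_C: float | None
    pct_I: float | None
    mode: str
    viewpoint: str
    reference_group: str
    column_labels: list[str]
    xbar1: np.ndarray
    xbar2: np.ndarray
    beta1: np.ndarray          # mode coefficients (logit or linear)
    beta2: np.ndarray
    lin_beta1: np.ndarray      # linear-probability coefficients (detail algebra)
    lin_beta2: np.ndarray
    fits: tuple[LogitFit, LogitFit] | None = None
    percents_defined: bool = True
    detailed: DetailedContribution | None = None
    ci: dict[str, tuple[float, float]] | None = None
    se: dict[str, float] | None = None
    n_bootstrap: int = 0
    n_bootstrap_failures: int = 0
    detailed_constant_ci: tuple[float, float] | None = None

    def components(self) -> dict[str, float]:
        return {"D": self.D, "E": self.E, "C": self.C, "I": self.I, "B": self.B}

    def to_dict(self) -> dict:
        out = {
            "mode": self.mode,
            "viewpoint": self.viewpoint,
            "reference_group": self.reference_group,
            "mean_pred_group1": self.mean_pred_group1,
            "mean_pred_group2": self.mean_pred_group2,
            **self.components(),
            "pct_E": self.pct_E, "pct_C": self.pct_C, "pct_I": self.pct_I,
            "n_bootstrap": self.n_bootstrap,
            "n_bootstrap_failures": self.n_bootstrap_failures,
        }
        if self.ci:
            out["ci"] = {k: list(v) for k, v in self.ci.items()}
        if self.se:
            out["se"] = dict(self.se)
        if self.detailed is not None:
            out["detailed"] = json.loads(
                self.detailed.table.to_json(orient="records"))
            out["detailed_constant_C"] = self.detailed.constant_C
        return out


def percent_contribution(part: float, D: float) -> float:
    """Sign-preserving percent of the gap: 100*part/D (D must be non-zero)."""
    if D == 0:
        raise DataError("percent contribution undefined: D = 0")
    return 100.0 * part / D


# ---------------------------------------------------------------------------
# Array-level core (shared by the user API and the bootstrap loop)
# ---------------------------------------------------------------------------

def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    H = (X * w[:, None]).T @ X
    try:
        return np.linalg.solve(H, X.T @ (w * y))
    except np.linalg.LinAlgError as exc:
        raise RankDeficiencyError(f"singular design in linear fit: {exc}") from exc


def _wmean(v: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(v * w) / np.sum(w))


def _decompose_core(
    X1, y1, w1, X2, y2, w2, labels, mode: str, viewpoint: str,
    want_fits: bool = False,
):
    """Components plus the linear-detail ingredients, on raw arrays."""
    xbar1 = (X1 * w1[:, None]).sum(axis=0) / w1.sum()
    xbar2 = (X2 * w2[:, None]).sum(axis=0) / w2.sum()
    lb1 = _wls(X1, y1, w1)
    lb2 = _wls(X2, y2, w2)

    fits = None
    if mode == "linear":
        b1, b2 = lb1, lb2
        p1 = float(lb1 @ xbar1)   # equals the weighted observed prevalence
        p2 = float(lb2 @ xbar2)
        D = p1 - p2
        dx, db = xbar1 - xbar2, b1 - b2
        if viewpoint == "group2":
            E = float(b2[1:] @ dx[1:])
            C = float(xbar2 @ db)
            I = float(dx[1:] @ db[1:])
        else:
            E = float(b1[1:] @ dx[1:])
            C = float(xbar1 @ db)
            I = -float(dx[1:] @ db[1:])
        B = float(db[0])
    elif mode == "logit_counterfactual":
        f1 = fit_logit_irls(X1, y1, w1, labels, group_tag="group1", check_rank=False)
        f2 = fit_logit_irls(X2, y2, w2, labels, group_tag="group2", check_rank=False)
        b1, b2 = f1.params, f2.params
        fits = (f1, f2)
        p11 = _wmean(expit(X1 @ b1), w1)
        p12 = _wmean(expit(X1 @ b2), w1)
        p21 = _wmean(expit(X2 @ b1), w2)
        p22 = _wmean(expit(X2 @ b2), w2)
        p1, p2 = p11, p22
        D = p11 - p22
        if viewpoint == "group2":
            E = p12 - p22
            C = p21 - p22
            b_swap = b2.copy()
            b_swap[0] = b1[0]
            B = _wmean(expit(X2 @ b_swap), w2) - p22
        else:
            E = p11 - p21
            C = p11 - p12
            b_swap = b1.copy()
            b_swap[0] = b2[0]
            B = p11 - _wmean(expit(X1 @ b_swap), w1)
        I = D - E - C
    else:
        raise DataError(f"unknown mode {mode!r}")

    return {
        "p1": p1, "p2": p2, "D": D, "E": E, "C": C, "I": I, "B": B,
        "xbar1": xbar1, "xbar2": xbar2, "beta1": b1, "beta2": b2,
        "lin_beta1": lb1, "lin_beta2": lb2,
        "fits": fits if want_fits else None,
    }


def _detail_parts(
    core: dict, labels: list[str], schema: CovariateSchema,
    covariates: list[str], viewpoint: str, normalization: str,
):
    """Per-level E/C parts from the linear-probability algebra.

    Returns (rows, constant_C) where rows are tuples
    (covariate, level, is_reference, E_part, C_part).
    ``as_encoded`` reports the k-1 dummy terms as fitted (reference rows 0);
    ``deviation`` re-expresses each covariate's coefficients as deviations
    from their level mean, removing reference-level dependence and spreading
    the contribution over all levels (component sums are unchanged).
    """
    xbar1, xbar2 = core["xbar1"], core["xbar2"]
    lb1, lb2 = core["lin_beta1"], core["lin_beta2"]
    by_label = {l: j for j, l in enumerate(labels)}
    xe = xbar1 if viewpoint == "group1" else xbar2   # means used by C
    be = lb1 if viewpoint == "group1" else lb2       # betas used by E

    rows = []
    constant_C = float(lb1[0] - lb2[0])
    for name in covariates:
        cov = schema.covariate(name)
        nonref = list(cov.nonreference_levels)
        idx = [by_label[f"{name}={l}"] for l in nonref]
        if normalization == "as_encoded":
            for level in cov.levels:
                if level == cov.reference:
                    rows.append((name, level, True, 0.0, 0.0))
                else:
                    j = by_label[f"{name}={level}"]
                    e = float(be[j] * (xbar1[j] - xbar2[j]))
                    c = float(xe[j] * (lb1[j] - lb2[j]))
                    rows.append((name, level, False, e, c))
        elif normalization == "deviation":
            # all-level coefficient vectors (reference coded 0), centred
            full1 = np.zeros(len(cov.levels))
            full2 = np.zeros(len(cov.levels))
            s1 = np.zeros(len(cov.levels))
            s2 = np.zeros(len(cov.levels))
            k_nonref = 0
            for k, level in enumerate(cov.levels):
                if level == cov.reference:
                    s1[k] = 1.0 - sum(xbar1[j] for j in idx)
                    s2[k] = 1.0 - sum(xbar2[j] for j in idx)
                else:
                    j = idx[k_nonref]
                    full1[k], full2[k] = lb1[j], lb2[j]
                    s1[k], s2[k] = xbar1[j], xbar2[j]
                    k_nonref += 1
            c1 = full1 - full1.mean()
            c2 = full2 - full2.mean()
            constant_C += float(full1.mean() - full2.mean())
            ce = c1 if viewpoint == "group1" else c2
            se_ = s1 if viewpoint == "group1" else s2
            for k, level in enumerate(cov.levels):
                e = float(ce[k] * (s1[k] - s2[k]))
                c = float(se_[k] * (c1[k] - c2[k]))
                rows.append((name, level, level == cov.reference, e, c))
        else:
            raise DataError(f"unknown normalization {normalization!r}")
    return rows, constant_C


def detailed_contributions(
    result: "DecompositionResult",
    schema: CovariateSchema,
    covariates: list[str],
    normalization: str = "as_encoded",
) -> DetailedContribution:
    """Allocate E and C to individual covariate levels (Constant row for B).

    Uses the linear-probability algebra; under the counterfactual mode the
    linear parts are rescaled by a single global factor per component so they
    sum to the counterfactual aggregates. Percents are suppressed when the
    gap is numerically zero.
    """
    core = {
        "xbar1": result.xbar1, "xbar2": result.xbar2,
        "lin_beta1": result.lin_beta1, "lin_beta2": result.lin_beta2,
    }
    rows, constant_C = _detail_parts(
        core, result.column_labels, schema, covariates,
        result.viewpoint, normalization,
    )
    e_parts = np.array([r[3] for r in rows])
    c_parts = np.array([r[4] for r in rows])
    if result.mode == "logit_counterfactual":
        e_sum = e_parts.sum()
        c_sum = c_parts.sum() + constant_C
        if abs(e_sum) > 1e-12:
            e_parts *= result.E / e_sum
        if abs(c_sum) > 1e-12:
            scale = result.C / c_sum
            c_parts *= scale
            constant_C *= scale

    defined = result.percents_defined
    table = pd.DataFrame({
        "covariate": [r[0] for r in rows],
        "level": [r[1] for r in rows],
        "is_reference": [r[2] for r in rows],
        "E_part": e_parts,
        "E_pct": [percent_contribution(e, result.D) if defined else np.nan
                  for e in e_parts],
        "C_part": c_parts,
        "C_pct": [percent_contribution(c, result.D) if defined else np.nan
                  for c in c_parts],
    })
    return DetailedContribution(
        table=table,
        constant_C=float(constant_C),
        constant_pct=(percent_contribution(constant_C, result.D)
                      if defined else None),
        normalization=normalization,
        mode=result.mode,
    )


# ---------------------------------------------------------------------------
# User-facing API
# ---------------------------------------------------------------------------

def _arrays(ds: AnalysisDataset, covariates: list[str] | None):
    covs = list(covariates) if covariates is not None else list(ds.schema.covariate_names)
    X, labels = encode_design_matrix(ds, covariates=covs)
    y, w = ds.outcome, ds.weights
    g1 = ds.group_mask(ds.schema.group_levels[0])
    return X, labels, y, w, g1, covs


def threefold_decompose(
    ds: AnalysisDataset,
    covariates: list[str] | None = None,
    mode: str = "logit_counterfactual",
    viewpoint: str = "group2",
    detailed: bool = True,
    normalization: str = "as_encoded",
) -> DecompositionResult:
    """Threefold decomposition of the group-1 minus group-2 prevalence gap.

    ``viewpoint="group2"`` (default) weights the endowment component by
    group-2 coefficients and evaluates the coefficient component at group-2
    means; ``"group1"`` mirrors the convention. Both group fits share one
    design layout spanning the full schema.
    """
    if viewpoint not in ("group1", "group2"):
        raise DataError("viewpoint must be 'group1' or 'group2'")
    X, labels, y, w, g1, covs = _arrays(ds, covariates)
    core = _decompose_core(
        X[g1], y[g1], w[g1], X[~g1], y[~g1], w[~g1],
        labels, mode, viewpoint, want_fits=True,
    )
    defined = abs(core["D"]) >= 1e-12
    ref_group = (ds.schema.group_levels[1] if viewpoint == "group2"
                 else ds.schema.group_levels[0])
    result = DecompositionResult(
        mean_pred_group1=core["p1"], mean_pred_group2=core["p2"],
        D=core["D"], E=core["E"], C=core["C"], I=core["I"], B=core["B"],
        pct_E=percent_contribution(core["E"], core["D"]) if defined else None,
        pct_C=percent_contribution(core["C"], core["D"]) if defined else None,
        pct_I=percent_contribution(core["I"], core["D"]) if defined else None,
        mode=mode, viewpoint=viewpoint, reference_group=ref_group,
        column_labels=labels,
        xbar1=core["xbar1"], xbar2=core["xbar2"],
        beta1=core["beta1"], beta2=core["beta2"],
        lin_beta1=core["lin_beta1"], lin_beta2=core["lin_beta2"],
        fits=core["fits"], percents_defined=defined,
    )
    if detailed:
        result.detailed = detailed_contributions(result, ds.schema, covs,
                                                 normalization)
    return result


def bootstrap_cis(
    ds: AnalysisDataset,
    covariates: list[str] | None = None,
    mode: str = "logit_counterfactual",
    viewpoint: str = "group2",
    B: int = 200,
    seed: int = 0,
    stratified: bool = True,
    alpha: float = 0.05,
    detailed: bool = True,
    normalization: str = "as_encoded",
    max_failure_fraction: float = 0.2,
) -> DecompositionResult:
    """Decomposition with percentile bootstrap intervals on every component.

    Records are resampled with replacement, by default within group
    (stratified) so both group fits always have data. Replicates that fail
    to fit (rank deficiency, separation, non-convergence) are logged and
    skipped; more than ``max_failure_fraction`` failures aborts. Fully
    deterministic for a fixed seed. Per-part intervals for the detailed table
    are attached as ``E_low/E_high/C_low/C_high`` columns.
    """
    if B < 100:
        raise DataError("bootstrap needs B >= 100 replicates")
    result = threefold_decompose(ds, covariates, mode, viewpoint,
                                 detailed=detailed, normalization=normalization)
    X, labels, y, w, g1, covs = _arrays(ds, covariates)
    i1, i2 = np.flatnonzero(g1), np.flatnonzero(~g1)
    n1, n2 = len(i1), len(i2)
    rng = np.random.default_rng(seed)

    comp_reps: dict[str, list[float]] = {k: [] for k in COMPONENTS}
    e_reps, c_reps, const_reps = [], [], []
    n_fail = 0
    for _ in range(B):
        if stratified:
            s1 = i1[rng.integers(0, n1, n1)]
            s2 = i2[rng.integers(0, n2, n2)]
        else:
            s = rng.integers(0, len(y), len(y))
            s1, s2 = s[np.isin(s, i1)], s[np.isin(s, i2)]
            if len(s1) == 0 or len(s2) == 0:
                n_fail += 1
                continue
        try:
            core = _decompose_core(X[s1], y[s1], w[s1], X[s2], y[s2], w[s2],
                                   labels, mode, viewpoint)
        except (DataError, np.linalg.LinAlgError):
            n_fail += 1
            continue
        for k in COMPONENTS:
            comp_reps[k].append(core[k])
        if detailed:
            rows, const_c = _detail_parts(core, labels, ds.schema, covs,
                                          viewpoint, normalization)
            ep = np.array([r[3] for r in rows])
            cp = np.array([r[4] for r in rows])
            if mode == "logit_counterfactual":
                if abs(ep.sum()) > 1e-12:
                    ep = ep * (core["E"] / ep.sum())
                tot_c = cp.sum() + const_c
                if abs(tot_c) > 1e-12:
                    cp = cp * (core["C"] / tot_c)
                    const_c *= core["C"] / tot_c
            e_reps.append(ep)
            c_reps.append(cp)
            const_reps.append(const_c)

    if n_fail > max_failure_fraction * B:
        raise UnstableResamplingError(
            f"unstable resampling: {n_fail}/{B} bootstrap replicates failed"
        )

    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    result.ci = {
        k: (float(np.percentile(v, lo)), float(np.percentile(v, hi)))
        for k, v in comp_reps.items()
    }
    result.se = {k: float(np.std(v, ddof=1)) for k, v in comp_reps.items()}
    result.n_bootstrap = B
    result.n_bootstrap_failures = n_fail
    if detailed and result.detailed is not None:
        E = np.vstack(e_reps)
        C = np.vstack(c_reps)
        t = result.detailed.table
        t["E_low"] = np.percentile(E, lo, axis=0)
        t["E_high"] = np.percentile(E, hi, axis=0)
        t["C_low"] = np.percentile(C, lo, axis=0)
        t["C_high"] = np.percentile(C, hi, axis=0)
        result.detailed.table = t
        cr = np.asarray(const_reps)
        result.detailed_constant_ci = (float(np.percentile(cr, lo)),
                                       float(np.percentile(cr, hi)))
    return result


def render_overall(result: DecompositionResult, schema: CovariateSchema,
                   decimals: int = 3) -> str:
    """Overall decomposition table: component, coefficient (CI), percent of D."""
    g1, g2 = schema.group_levels

    def ci_str(k):
        if not result.ci or k not in result.ci:
            return ""
        lo, hi = result.ci[k]
        return f"({lo:.{decimals}f}, {hi:.{decimals}f})"

    rows = [
        (f"{g1} mean prediction", result.mean_pred_group1, "", ""),
        (f"{g2} mean prediction", result.mean_pred_group2, "", ""),
        ("Difference (D)", result.D, ci_str("D"), ""),
        ("Endowment (E)", result.E, ci_str("E"),
         "" if result.pct_E is None else f"{result.pct_E:.1f}"),
        ("Coefficient (C)", result.C, ci_str("C"),
         "" if result.pct_C is None else f"{result.pct_C:.1f}"),
        ("Interaction (I)", result.I, ci_str("I"),
         "" if result.pct_I is None else f"{result.pct_I:.1f}"),
    ]
    df = pd.DataFrame(rows, columns=["component", "coefficient", "95% CI",
                                     "pct contribution"])
    df["coefficient"] = df["coefficient"].map(lambda v: f"{v:.{decimals}f}")
    return df.to_string(index=False)
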