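"""Synthetic two-group survey generator with a known decomposition truth.

Emulates a DHS-style women's sample: two residence groups with different
categorical covariate mixes, group-specific logit coefficients linking the
covariates to a Bernoulli overweight/obesity outcome, positive sampling
weights, and pregnancy / missing-BMI flags so the exclusion pipeline is
exercised end to end. Because the data-generating process is known, the true
endowment / coefficient / interaction split of the group gap can be computed
by Monte-Carlo integration over the covariate mixes, giving every downstream
estimator an oracle to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .data_model import Covariate, CovariateSchema, DataError


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the two-group logit data-generating process.

    ``mix_group1`` / ``mix_group2`` give, per covariate, a probability vector
    over its levels (in level order). ``beta_group1`` / ``beta_group2`` are
    log-odds coefficients keyed by design-column label (``"constant"`` plus
    ``"covariate=level"`` for every non-reference level); both groups share
    one column layout. Sampling weights are Gamma with mean 1 (shape
    ``weight_shape``); ``weight_group2_scale`` optionally multiplies group-2
    weights to make weighting informative, for testing weighted estimators.
    """

    n: int
    p_group1: float
    covariates: tuple[Covariate, ...]
    mix_group1: Mapping[str, tuple[float, ...]]
    mix_group2: Mapping[str, tuple[float, ...]]
    beta_group1: Mapping[str, float]
    beta_group2: Mapping[str, float]
    weight_shape: float = 4.0
    weight_group2_scale: float = 1.0
    pregnancy_rate: float = 0.0
    missing_bmi_rate: float = 0.0
    seed: int = 0
    group_variable: str = "residence"
    group_levels: tuple[str, str] = ("urban", "rural")

    def __post_init__(self) -> None:
        if not 0 < self.p_group1 < 1:
            raise DataError("p_group1 must be strictly between 0 and 1")
        for rate in (self.pregnancy_rate, self.missing_bmi_rate):
            if not 0 <= rate < 1:
                raise DataError("rates must lie in [0, 1)")
        for label, mix in (("group1", self.mix_group1), ("group2", self.mix_group2)):
            if set(mix) != set(c.name for c in self.covariates):
                raise DataError(f"mix_{label} must cover every covariate exactly")
            for c in self.covariates:
                p = np.asarray(mix[c.name], float)
                if len(p) != len(c.levels) or np.any(p < 0):
                    raise DataError(
                        f"mix_{label}[{c.name!r}] needs one probability per level"
                    )
                if abs(p.sum() - 1.0) > 1e-12:
                    raise DataError(
                        f"mix_{label}[{c.name!r}] must sum to 1 within 1e-12"
                    )
        expected = set(self.design_labels())
        for label, beta in (("group1", self.beta_group1), ("group2", self.beta_group2)):
            if set(beta) != expected:
                raise DataError(
                    f"beta_{label} keys must match the design columns {sorted(expected)}"
                )

    def design_labels(self) -> list[str]:
        labels = ["constant"]
        for c in self.covariates:
            labels += [f"{c.name}={l}" for l in c.nonreference_levels]
        return labels

    def schema(self) -> CovariateSchema:
        return CovariateSchema(
            covariates=self.covariates,
            group_variable=self.group_variable,
            group_levels=self.group_levels,
        )

    def beta_vector(self, group: int) -> np.ndarray:
        beta = self.beta_group1 if group == 1 else self.beta_group2
        return np.array([beta[l] for l in self.design_labels()])

    def mean_design_vector(self, group: int) -> np.ndarray:
        """Expected dummy vector under the group's covariate mix (closed form)."""
        mix = self.mix_group1 if group == 1 else self.mix_group2
        out = [1.0]
        for c in self.covariates:
            probs = dict(zip(c.levels, mix[c.name]))
            out += [probs[l] for l in c.nonreference_levels]
        return np.array(out)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "p_group1": self.p_group1,
            "covariates": [
                {"name": c.name, "levels": list(c.levels), "reference": c.reference}
                for c in self.covariates
            ],
            "mix_group1": {k: list(v) for k, v in self.mix_group1.items()},
            "mix_group2": {k: list(v) for k, v in self.mix_group2.items()},
            "beta_group1": dict(self.beta_group1),
            "beta_group2": dict(self.beta_group2),
            "weight_shape": self.weight_shape,
            "weight_group2_scale": self.weight_group2_scale,
            "pregnancy_rate": self.pregnancy_rate,
            "missing_bmi_rate": self.missing_bmi_rate,
            "seed": self.seed,
            "group_variable": self.group_variable,
            "group_levels": list(self.group_levels),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        d["covariates"] = tuple(
            Covariate(c["name"], tuple(c["levels"]), c["reference"])
            for c in d["covariates"]
        )
        d["mix_group1"] = {k: tuple(v) for k, v in d["mix_group1"].items()}
        d["mix_group2"] = {k: tuple(v) for k, v in d["mix_group2"].items()}
        d["group_levels"] = tuple(d.get("group_levels", ("urban", "rural")))
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def replace(self, **kw) -> "SyntheticConfig":
        d = self.to_dict()
        d.update(kw)
        return SyntheticConfig.from_dict(d)


@dataclass(frozen=True)
class SyntheticTruth:
    """Oracle decomposition components of a :class:`SyntheticConfig`.

    Probability-scale components come from Monte-Carlo integration over the
    covariate mixes (``oracle_se`` gives the per-component Monte-Carlo
    standard error); linear-index-scale components are closed-form in the
    mean dummy vectors and coefficients. ``B_true`` isolates the intercept
    (unobservables) share of the coefficient effect; the three-component
    display folds it into ``C_true``.
    """

    D_true: float
    E_true: float
    C_true: float
    I_true: float
    B_true: float
    mean_outcome_group1: float
    mean_outcome_group2: float
    oracle_n: int
    oracle_se: dict[str, float]
    linear: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "D_true": self.D_true, "E_true": self.E_true, "C_true": self.C_true,
            "I_true": self.I_true, "B_true": self.B_true,
            "mean_outcome_group1": self.mean_outcome_group1,
            "mean_outcome_group2": self.mean_outcome_group2,
            "oracle_n": self.oracle_n, "oracle_se": dict(self.oracle_se),
            "linear": dict(self.linear),
        }


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _draw_levels(rng, cov: Covariate, mix: Sequence[float], size: int) -> np.ndarray:
    """Level indices drawn from one covariate's mix."""
    cum = np.cumsum(np.asarray(mix, float))
    cum[-1] = 1.0
    return np.searchsorted(cum, rng.random(size), side="right")


def _linear_predictor(cfg: SyntheticConfig, level_idx: dict[str, np.ndarray],
                      beta: Mapping[str, float]) -> np.ndarray:
    n = len(next(iter(level_idx.values())))
    lp = np.full(n, beta["constant"])
    for c in cfg.covariates:
        per_level = np.array([
            beta[f"{c.name}={l}"] if l != c.reference else 0.0 for l in c.levels
        ])
        lp += per_level[level_idx[c.name]]
    return lp


def generate_sample(cfg: SyntheticConfig, seed: int | None = None):
    """Draw ``cfg.n`` survey records; fully reproducible from the seed.

    Returns a pandas DataFrame in the CSV dialect of :mod:`data_model`:
    ``id``, group label, covariate labels, ``bmi`` (missing at the configured
    rate), ``pregnant`` flag, ``weight``, and the generating ``outcome`` —
    the BMI is synthesised on the correct side of 25 so deriving the outcome
    from BMI reproduces the Bernoulli draw exactly.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n
    in_group1 = rng.random(n) < cfg.p_group1
    if in_group1.all() or not in_group1.any():
        raise DataError("degenerate group draw: only one group present; increase n")

    level_idx: dict[str, np.ndarray] = {}
    for c in cfg.covariates:
        idx = np.empty(n, dtype=np.int64)
        idx[in_group1] = _draw_levels(rng, c, cfg.mix_group1[c.name], int(in_group1.sum()))
        idx[~in_group1] = _draw_levels(rng, c, cfg.mix_group2[c.name], int((~in_group1).sum()))
        level_idx[c.name] = idx

    lp = np.where(
        in_group1,
        _linear_predictor(cfg, level_idx, cfg.beta_group1),
        _linear_predictor(cfg, level_idx, cfg.beta_group2),
    )
    if not np.all(np.isfinite(lp)):
        raise DataError("non-finite linear predictor: coefficients too extreme")
    outcome = (rng.random(n) < expit(lp)).astype(int)

    # BMI synthesised consistently with the drawn outcome (kg/m^2)
    bmi = np.where(
        outcome == 1,
        25.0 + rng.gamma(2.0, 2.5, n),          # overweight/obese: mean 30
        16.0 + 8.9 * rng.beta(2.0, 2.0, n),     # below threshold: mean ~20.5
    ).round(1)
    bmi = np.minimum(bmi, np.where(outcome == 1, np.inf, 24.9))

    weight = rng.gamma(cfg.weight_shape, 1.0 / cfg.weight_shape, n)
    if cfg.weight_group2_scale != 1.0:
        weight = np.where(in_group1, weight, weight * cfg.weight_group2_scale)

    pregnant = (rng.random(n) < cfg.pregnancy_rate).astype(int)
    missing = rng.random(n) < cfg.missing_bmi_rate
    bmi = np.where(missing, np.nan, bmi)

    df = pd.DataFrame({"id": np.arange(1, n + 1)})
    df[cfg.group_variable] = np.where(in_group1, cfg.group_levels[0], cfg.group_levels[1])
    for c in cfg.covariates:
        df[c.name] = np.asarray(c.levels, object)[level_idx[c.name]]
    df["bmi"] = bmi
    df["pregnant"] = pregnant
    df["weight"] = weight
    df["outcome"] = np.where(np.isnan(bmi), np.nan, outcome)
    return df


# ---------------------------------------------------------------------------
# Truth oracle
# ---------------------------------------------------------------------------

def compute_truth(
    cfg: SyntheticConfig,
    oracle_n: int = 1_000_000,
    seed: int | None = None,
    se_tol: float | None = None,
    chunk: int = 1_000_000,
) -> SyntheticTruth:
    """Monte-Carlo ground truth for the threefold decomposition.

    Draws ``oracle_n`` covariate vectors from each group's mix and averages
    inverse-logit predictions under each (mix, coefficient-vector) pairing:
    the endowment effect contrasts the two mixes under group-2 coefficients,
    the coefficient effect contrasts the two coefficient vectors at the
    group-2 mix, the interaction is the residual, and the intercept-only
    share ``B_true`` comes from a fifth pairing that swaps intercepts only.
    Linear-index-scale components are exact in the mean dummy vectors.
    """
    rng = np.random.default_rng(cfg.seed + 104729 if seed is None else seed)
    sums = {k: 0.0 for k in ("D", "E", "C", "I", "B", "p1", "p2")}
    sumsq = {k: 0.0 for k in ("D", "E", "C", "I", "B")}
    b1, b2 = dict(cfg.beta_group1), dict(cfg.beta_group2)
    b_swap = dict(b2)
    b_swap["constant"] = b1["constant"]

    done = 0
    while done < oracle_n:
        m = min(chunk, oracle_n - done)
        x1 = {c.name: _draw_levels(rng, c, cfg.mix_group1[c.name], m)
              for c in cfg.covariates}
        x2 = {c.name: _draw_levels(rng, c, cfg.mix_group2[c.name], m)
              for c in cfg.covariates}
        p11 = expit(_linear_predictor(cfg, x1, b1))
        p12 = expit(_linear_predictor(cfg, x1, b2))
        p21 = expit(_linear_predictor(cfg, x2, b1))
        p22 = expit(_linear_predictor(cfg, x2, b2))
        p2b = expit(_linear_predictor(cfg, x2, b_swap))
        per_draw = {
            "D": p11 - p22, "E": p12 - p22, "C": p21 - p22, "B": p2b - p22,
        }
        per_draw["I"] = per_draw["D"] - per_draw["E"] - per_draw["C"]
        for k, v in per_draw.items():
            sums[k] += float(v.sum())
            sumsq[k] += float((v * v).sum())
        sums["p1"] += float(p11.sum())
        sums["p2"] += float(p22.sum())
        done += m

    means = {k: sums[k] / oracle_n for k in sums}
    se = {
        k: float(np.sqrt(max(sumsq[k] / oracle_n - means[k] ** 2, 0.0) / oracle_n))
        for k in sumsq
    }
    if se_tol is not None and max(se.values()) > se_tol:
        raise DataError(
            f"oracle standard error {max(se.values()):.2e} exceeds {se_tol:.2e}; "
            f"increase oracle_n"
        )

    # closed-form linear-index-scale components
    xb1, xb2 = cfg.mean_design_vector(1), cfg.mean_design_vector(2)
    v1, v2 = cfg.beta_vector(1), cfg.beta_vector(2)
    dx, db = xb1 - xb2, v1 - v2
    linear = {
        "D": float(v1 @ xb1 - v2 @ xb2),
        "E": float(v2[1:] @ dx[1:]),
        "C": float(xb2 @ db),           # includes the intercept term B
        "I": float(dx[1:] @ db[1:]),
        "B": float(db[0]),
    }

    return SyntheticTruth(
        D_true=means["D"], E_true=means["E"], C_true=means["C"],
        I_true=means["I"], B_true=means["B"],
        mean_outcome_group1=means["p1"], mean_outcome_group2=means["p2"],
        oracle_n=oracle_n, oracle_se=se, linear=linear,
    )


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def default_config(n: int = 20_000, seed: int = 2018, **overrides) -> SyntheticConfig:
    """A DHS-like two-group configuration.

    Mixes and coefficients emulate a West-African women's survey: the urban
    group is wealthier, more educated and more media-exposed, and both the
    covariate mixes and the returns to them differ by residence, so all three
    decomposition components are non-zero. Group shares and outcome levels
    are set so urban/rural overweight-obesity prevalences come out near
    0.35 / 0.21 with an urban share near 42%.
    """
    covs = (
        Covariate("wealth", ("poor", "middle", "rich"), "poor"),
        Covariate("age_group", ("15-24", "25-34", "35-49"), "15-24"),
        Covariate("education", ("none", "primary", "secondary", "tertiary"), "none"),
        Covariate("media_exposure", ("not_exposed", "exposed"), "not_exposed"),
        Covariate("contraceptive_use", ("non_user", "user"), "non_user"),
    )
    mix1 = {
        "wealth": (0.17, 0.22, 0.61),
        "age_group": (0.33, 0.33, 0.34),
        "education": (0.14, 0.14, 0.52, 0.20),
        "media_exposure": (0.15, 0.85),
        "contraceptive_use": (0.12, 0.88),
    }
    mix2 = {
        "wealth": (0.48, 0.22, 0.30),
        "age_group": (0.36, 0.31, 0.33),
        "education": (0.43, 0.18, 0.33, 0.06),
        "media_exposure": (0.43, 0.57),
        "contraceptive_use": (0.20, 0.80),
    }
    beta1 = {
        "constant": -3.44,
        "wealth=middle": 0.59, "wealth=rich": 1.28,
        "age_group=25-34": 0.84, "age_group=35-49": 1.34,
        "education=primary": 0.23, "education=secondary": 0.38,
        "education=tertiary": 0.85,
        "media_exposure=exposed": 0.49,
        "contraceptive_use=user": 0.33,
    }
    beta2 = {
        "constant": -3.35,
        "wealth=middle": 0.55, "wealth=rich": 1.20,
        "age_group=25-34": 0.80, "age_group=35-49": 1.30,
        "education=primary": 0.20, "education=secondary": 0.35,
        "education=tertiary": 0.80,
        "media_exposure=exposed": 0.45,
        "contraceptive_use=user": 0.30,
    }
    cfg = SyntheticConfig(
        n=n, p_group1=0.42, covariates=covs,
        mix_group1=mix1, mix_group2=mix2,
        beta_group1=beta1, beta_group2=beta2,
        weight_shape=4.0, pregnancy_rate=0.07, missing_bmi_rate=0.03,
        seed=seed,
    )
    return cfg.replace(**overrides) if overrides else cfg
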