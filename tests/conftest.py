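"""Shared fixtures: toy schemas, weighted-cell dataset builders, synthetic samples."""

import numpy as np
import pandas as pd
import pytest

import healthgap as hg


@pytest.fixture
def toy_schema():
    """Two covariates (3 and 2 levels) plus a two-level residence group."""
    return hg.CovariateSchema(
        covariates=(
            hg.Covariate("wealth", ("poor", "middle", "rich"), "poor"),
            hg.Covariate("media", ("not_exposed", "exposed"), "not_exposed"),
        ),
        group_variable="residence",
        group_levels=("urban", "rural"),
    )


@pytest.fixture
def toy_frame(toy_schema):
    """13 hand-written records; level tallies are easy to count by eye."""
    rows = [
        # residence, wealth, media, bmi, pregnant, weight
        ("urban", "poor", "exposed", 27.1, 0, 1.0),
        ("urban", "middle", "exposed", 31.4, 0, 1.2),
        ("urban", "rich", "exposed", 24.2, 0, 0.8),
        ("urban", "rich", "not_exposed", 29.0, 0, 1.1),
        ("urban", "poor", "not_exposed", 21.5, 0, 0.9),
        ("urban", "middle", "exposed", 26.0, 0, 1.0),
        ("rural", "poor", "not_exposed", 20.3, 0, 1.3),
        ("rural", "poor", "not_exposed", 25.5, 0, 1.0),
        ("rural", "middle", "exposed", 23.0, 0, 0.7),
        ("rural", "rich", "exposed", 28.8, 0, 1.1),
        ("rural", "poor", "exposed", 19.9, 0, 1.0),
        ("rural", "middle", "not_exposed", 24.9, 0, 1.0),
        ("rural", "rich", "not_exposed", 26.6, 0, 0.9),
    ]
    return pd.DataFrame(
        rows, columns=["residence", "wealth", "media", "bmi", "pregnant", "weight"]
    )


@pytest.fixture
def toy_dataset(toy_frame, toy_schema):
    return hg.apply_exclusions(toy_frame, toy_schema)


def cell_dataset(cells, covariate_names=(), group_levels=("urban", "rural")):
    """Build an AnalysisDataset from weighted cells.

    ``cells`` is a list of (group, covariate-levels-tuple, outcome, weight).
    Weighted likelihoods make one weighted row equivalent to `weight` unit
    rows, so printed survey counts can stand in for record-level data.
    """
    covs = {}
    for _, levels, _, _ in cells:
        for name, level in zip(covariate_names, levels):
            covs.setdefault(name, [])
            if level not in covs[name]:
                covs[name].append(level)
    schema = hg.CovariateSchema(
        covariates=tuple(
            hg.Covariate(n, tuple(levels), levels[0]) for n, levels in covs.items()
        ),
        group_variable="residence",
        group_levels=group_levels,
    )
    rows = []
    for group, levels, outcome, weight in cells:
        row = {"residence": group, "outcome": outcome, "weight": weight}
        row.update(dict(zip(covariate_names, levels)))
        rows.append(row)
    return hg.apply_exclusions(pd.DataFrame(rows), schema)


# Printed residence x outcome counts from the survey's published tables:
# urban 1994 overweight/obese of 5611, rural 1634 of 7728 (N = 13,339).
RESIDENCE_COUNTS = {
    ("urban", 1): 1994, ("urban", 0): 5611 - 1994,
    ("rural", 1): 1634, ("rural", 0): 7728 - 1634,
}
# contraceptive use x outcome: users 2638 of 11080, non-users 990 of 2259
CONTRACEPTIVE_COUNTS = np.array([[2638, 11080 - 2638], [990, 2259 - 990]])


@pytest.fixture
def residence_dataset():
    """Unit-weight reconstruction of the published residence x outcome table."""
    cells = []
    for (g, y), n in RESIDENCE_COUNTS.items():
        cells.extend([(g, (), y, 1.0)] * n)
    return cell_dataset(cells)


@pytest.fixture(scope="session")
def small_sample():
    """One mid-sized draw from the default DHS-like generator, shared per session."""
    cfg = hg.default_config(n=12_000, seed=421)
    raw = hg.generate_sample(cfg)
    ds = hg.apply_exclusions(raw.drop(columns=["outcome"]), cfg.schema())
    return cfg, raw, ds
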