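"""Shared fixtures: one small simulated study reused across test modules."""

import numpy as np
import pytest

import beetgs as b


@pytest.fixture(scope="session")
def small_study():
    """Scaled-down study: 200 diversity lines + 2 x 40-progeny families."""
    design = b.PopulationDesign(
        n_diversity=200,
        families=(b.FamilySpec("Family1", 40), b.FamilySpec("Family2", 40)),
    )
    return b.simulate_study(
        seed=20260928,
        design=design,
        n_markers=250,
        n_qtl=15,
        traits={"T": 0.6},
    )


@pytest.fixture(scope="session")
def small_blues(small_study):
    """(marker matrix, variance components, BLUEs aligned to lines)."""
    rec = small_study.phenotypes["T"]
    vc = b.fit_variance_components(rec)
    blues = b.estimate_blues(rec)
    mm = small_study.marker_matrix()
    y = blues.loc[mm.line_ids].to_numpy()
    return mm, vc, y


def make_balanced_records(
    n_lines, n_locs, sigma_g, sigma_l, sigma_e, seed, mu=10.0
):
    """Balanced one-record-per-cell table drawn from the entry-mean model."""
    rng = np.random.default_rng(seed)
    g = rng.normal(0, sigma_g, n_lines)
    loc = rng.normal(0, sigma_l, n_locs)
    rows = []
    for i in range(n_lines):
        for j in range(n_locs):
            rows.append(
                (f"L{i:04d}", f"E{j}", mu + g[i] + loc[j] + rng.normal(0, sigma_e))
            )
    import pandas as pd

    df = pd.DataFrame(rows, columns=["line_id", "location_id", "value"])
    return b.PhenotypeRecords(df, trait="sim")


def anova_moments(records):
    """Closed-form balanced two-way ANOVA moment estimators (the REML oracle).

    sigma_G^2 = (MS_G - MS_E)/J, sigma_L^2 = (MS_L - MS_E)/N with MS_E from
    the interaction/residual stratum; valid for balanced one-obs-per-cell
    tables with interior (non-negative) solutions.
    """
    df = records.df
    piv = df.pivot(index="line_id", columns="location_id", values="value")
    N, J = piv.shape
    y = piv.to_numpy()
    grand = y.mean()
    line_means = y.mean(axis=1)
    loc_means = y.mean(axis=0)
    ss_g = J * ((line_means - grand) ** 2).sum()
    ss_l = N * ((loc_means - grand) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_e = ss_tot - ss_g - ss_l
    ms_g = ss_g / (N - 1)
    ms_l = ss_l / (J - 1)
    ms_e = ss_e / ((N - 1) * (J - 1))
    return (ms_g - ms_e) / J, (ms_l - ms_e) / N, ms_e
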