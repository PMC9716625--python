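"""Eye-gaze fixation aggregation over areas of interest (AOI).

Five AOIs cover each stimulus display: the head and the upper body (arms,
hands and instrument) of each musician, plus the screen centre.  Fixation
samples already carry their AOI label (the gaze-to-AOI assignment is an
upstream, manual step); this module turns labelled samples into percentage
fixation time per 1 s bin, averages the bins per participant x stimulus x
AOI, and models the means by AOI and music training.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["AOIS", "fixation_percentages", "fit_fixation_model"]

AOIS = ("P_Head", "P_UpperBody", "S_Head", "S_UpperBody", "Center")


def fixation_percentages(
    samples: pd.DataFrame,
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """Mean percentage fixation time per participant x stimulus x AOI.

    ``samples`` has columns ``participant, stimulus, t, aoi`` where ``aoi``
    is one of :data:`AOIS` or ``"none"`` (gaze off every AOI / untracked).
    Percentages within a bin are taken over the *tracked* samples (those with
    any AOI), so they sum to 100% per bin; bins are then averaged within each
    trial, with a partial final bin weighted by its tracked-sample share.
    An empty trial yields an all-NaN row and is reported via the ``n_bins``
    column being 0.
    """
    bad = set(samples["aoi"].unique()) - set(AOIS) - {"none"}
    if bad:
        raise ValueError(f"unknown AOI labels: {sorted(bad)}")
    out_rows = []
    for (pid, sid), trial in samples.groupby(["participant", "stimulus"]):
        tracked = trial[trial["aoi"] != "none"]
        if len(tracked) == 0:
            for aoi in AOIS:
                out_rows.append(
                    {
                        "participant": pid,
                        "stimulus": sid,
                        "aoi": aoi,
                        "mean_pct": np.nan,
                        "n_bins": 0,
                    }
                )
            continue
        bins = np.floor(tracked["t"].to_numpy(float) / bin_width).astype(int)
        counts = (
            pd.DataFrame({"bin": bins, "aoi": tracked["aoi"].to_numpy()})
            .groupby(["bin", "aoi"])
            .size()
            .unstack(fill_value=0)
            .reindex(columns=list(AOIS), fill_value=0)
        )
        tracked_totals = counts.sum(axis=1)
        pct = counts.div(tracked_totals, axis=0) * 100.0
        # bins weighted by wall-time coverage: full bins count 1, the partial
        # final bin counts its sample share (tracked share within a bin does
        # not change its weight — percentages are of tracked time)
        wall = (
            pd.Series(np.floor(trial["t"].to_numpy(float) / bin_width).astype(int))
            .value_counts()
            .reindex(counts.index, fill_value=0)
        )
        weights = (wall / wall.max()).to_numpy()
        mean_pct = (pct.mul(weights, axis=0)).sum(axis=0) / weights.sum()
        for aoi in AOIS:
            out_rows.append(
                {
                    "participant": pid,
                    "stimulus": sid,
                    "aoi": aoi,
                    "mean_pct": float(mean_pct[aoi]),
                    "n_bins": int(len(counts)),
                }
            )
    return pd.DataFrame(out_rows)


def fit_fixation_model(
    means: pd.DataFrame,
    reference_aoi: str = "S_UpperBody",
    training_col: str = "background",
):
    """Linear mixed model of mean fixation percentage by AOI and training.

    Fixed effects: AOI (treatment-coded against ``reference_aoi``) and music
    training; crossed random intercepts for participant and stimulus
    (statsmodels MixedLM variance components).  Returns the fitted
    MixedLMResults; a singular fit is flagged by the usual statsmodels
    convergence warnings rather than raising.
    """
    import statsmodels.formula.api as smf

    data = means.dropna(subset=["mean_pct"]).copy()
    if data["aoi"].nunique() < 2:
        raise ValueError("need at least two AOI levels")
    formula = (
        f"mean_pct ~ C(aoi, Treatment('{reference_aoi}')) + C({training_col})"
    )
    model = smf.mixedlm(
        formula,
        data=data,
        groups=np.ones(len(data)),
        vc_formula={
            "participant": "0 + C(participant)",
            "stimulus": "0 + C(stimulus)",
        },
    )
    return model.fit(reml=True, method="lbfgs")
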