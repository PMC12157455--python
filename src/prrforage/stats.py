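"""Optional convenience wrapper for routine mixed-effects fits.

Session-level inference (task effects on counts, latencies, bout lengths)
is ordinary repeated-measures regression and is delegated entirely to
statsmodels; nothing here is part of the analysis contribution.
"""

from __future__ import annotations

import pandas as pd


def fit_mixed_model(data: pd.DataFrame, formula: str, groups: str = "subject_id"):
    """Fit a linear mixed-effects model with a random intercept per subject.

    Thin delegation to ``statsmodels.formula.api.mixedlm``; returns the
    fitted results object.  Requires statsmodels (``prrforage[stats]``).
    """
    import statsmodels.formula.api as smf

    used = [c for c in data.columns if c in formula]
    df = data.dropna(subset=used) if used else data
    model = smf.mixedlm(formula, data=df, groups=df[groups])
    return model.fit()
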