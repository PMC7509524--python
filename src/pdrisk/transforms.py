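"""Rank-based inverse normal transformation (Blom offset).

Maps a variable to standard-normal quantiles via
``z_i = Phi^{-1}((r_i - 3/8) / (n + 1/4))`` where ``r_i`` is the average rank
(ties share their mean rank).  Used to normalise the polygenic score and
continuous exposures (e.g. age at menarche) before interaction modelling.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def inverse_normal_transform(values) -> np.ndarray:
    """Blom rank-based inverse normal transform; NaNs are propagated.

    Raises ``ValueError`` when fewer than two distinct finite values are
    present (the transform is undefined on a constant).
    """
    x = np.asarray(values, dtype=float)
    finite = ~np.isnan(x)
    if np.unique(x[finite]).size < 2:
        raise ValueError("inverse normal transform requires >= 2 distinct values")
    out = np.full(x.shape, np.nan)
    ranks = stats.rankdata(x[finite], method="average")
    n = finite.sum()
    out[finite] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return out
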