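"""Scale transforms between methylation beta values and M-values (logits).

Beta values live on [0, 1]; additive models (batch adjustment, simulation)
operate on the unbounded logit scale. Clipping keeps the transform finite at
the boundaries; the clip bound is well inside float64 resolution so the
round trip is exact to ~1e-12 on the open interval.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit

#: beta values are clipped into [BETA_EPS, 1 - BETA_EPS] before logit
BETA_EPS = 1e-6

#: logits are clipped to +/- LOGIT_MAX so expit() stays strictly inside (0, 1)
LOGIT_MAX = 30.0


def beta_to_m(beta: np.ndarray, eps: float = BETA_EPS) -> np.ndarray:
    """Logit-transform beta values, clipping into [eps, 1 - eps] first."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    return logit(b)


def m_to_beta(m: np.ndarray, max_abs: float = LOGIT_MAX) -> np.ndarray:
    """Inverse-logit back to the beta scale; output strictly inside (0, 1)."""
    x = np.clip(np.asarray(m, dtype=float), -max_abs, max_abs)
    return expit(x)
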