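"""Independent oracles kept deliberately separate from the package.

``constrained_apc_fit`` resolves the APC identification problem the
just-identified way — dummy coding with the first two cohort levels
equated — instead of the minimum-norm projection.  Second differences
of effect curves are estimable, so both routes must agree on them even
though the effect levels themselves differ.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm


def constrained_apc_fit(deaths: np.ndarray, person_years: np.ndarray):
    """Just-identified Poisson APC fit (cohorts 1 and 2 equated).

    Dummy coding with the last level of each block as reference.
    Returns (age, period, cohort) effect vectors on that
    identification plus the residual deviance.
    """
    A, P = deaths.shape
    C = A + P - 1
    rows = []
    for i in range(1, A + 1):
        for j in range(1, P + 1):
            k = A - i + j
            age = [1.0 if i == a else 0.0 for a in range(1, A)]
            per = [1.0 if j == p else 0.0 for p in range(1, P)]
            # cohort dummies for levels 2..C-1; level-2 column also
            # absorbs level 1 (the equality constraint); level C = ref
            coh = [1.0 if (k == c or (c == 2 and k == 1)) else 0.0 for c in range(2, C)]
            rows.append([1.0] + age + per + coh)
    X = np.array(rows)
    res = sm.GLM(
        deaths.reshape(-1),
        X,
        family=sm.families.Poisson(),
        offset=np.log(person_years.reshape(-1)),
    ).fit(method="IRLS", maxiter=200, tol=1e-12)

    b = res.params
    pos = 1
    age = np.concatenate([b[pos : pos + A - 1], [0.0]])
    pos += A - 1
    period = np.concatenate([b[pos : pos + P - 1], [0.0]])
    pos += P - 1
    coh_coefs = b[pos : pos + C - 2]
    cohort = np.concatenate([[coh_coefs[0], coh_coefs[0]], coh_coefs[1:], [0.0]])
    return age, period, cohort, float(res.deviance)


def poisson_deviance_closed_form(observed, fitted) -> float:
    """2 * sum[d log(d / mu) - (d - mu)] with 0 log 0 = 0, coded afresh."""
    total = 0.0
    for d, mu in zip(np.ravel(observed), np.ravel(fitted)):
        if d > 0:
            total += d * np.log(d / mu)
        total -= d - mu
    return 2.0 * total
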