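"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's own fast paths: concentrations are
integrated from the two-state absorption/elimination ODE system, and the
marginal likelihood is computed by adaptive Gauss-Hermite quadrature over
the random effects.  They are slow and only run on tiny instances.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize
from scipy.integrate import solve_ivp

from siropk.pk import concentration_profile, individual_params


def ode_concentration(cl: float, v: float, ka: float, amount_mg: float, times) -> np.ndarray:
    """Concentration (ng/ml) from numerically integrating the ODE system.

    dA_gut/dt = -ka*A_gut ; dA_c/dt = ka*A_gut - ke*A_c, dose in the gut at t=0.
    """
    ke = cl / v
    times = np.atleast_1d(np.asarray(times, dtype=float))
    t_end = max(times.max(), 1e-6)
    sol = solve_ivp(
        lambda t, y: [-ka * y[0], ka * y[0] - ke * y[1]],
        [0.0, t_end],
        [amount_mg * 1e3, 0.0],
        rtol=1e-11,
        atol=1e-13,
        dense_output=True,
    )
    return sol.sol(times)[1] / v


def quadrature_ofv(dataset, model, n_nodes: int = 40) -> float:
    """-2 log marginal likelihood by adaptive Gauss-Hermite quadrature.

    Centres and scales the node grid at each subject's joint mode and
    curvature; accuracy is limited only by the node count (>= 32 per
    dimension for the instances used in tests).
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    omega2 = np.array([model.omega2_cl, model.omega2_v])
    active = omega2 > 1e-12
    total = 0.0
    for s in dataset:
        def neg_log_joint(eta_active):
            eta = np.zeros(2)
            eta[active] = eta_active
            p = individual_params(model, s.weight, eta[0], eta[1], covariates=s.covariates)
            f = concentration_profile(p, s.doses, s.obs_times)
            var = f**2 * model.sigma2_prop + model.sigma2_add
            ll = -0.5 * np.sum(np.log(2 * np.pi * var) + (s.obs_conc - f) ** 2 / var)
            lp = -0.5 * np.sum(
                eta[active] ** 2 / omega2[active] + np.log(2 * np.pi * omega2[active])
            )
            return -(ll + lp)

        k = int(active.sum())
        if k == 0:
            total += 2.0 * neg_log_joint(np.zeros(0))
            continue
        res = optimize.minimize(
            neg_log_joint, np.zeros(k), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        mu = res.x
        h = 1e-4
        H = np.zeros((k, k))
        for i in range(k):
            for j in range(k):
                ei = np.zeros(k); ei[i] = h
                ej = np.zeros(k); ej[j] = h
                H[i, j] = (
                    neg_log_joint(mu + ei + ej) - neg_log_joint(mu + ei - ej)
                    - neg_log_joint(mu - ei + ej) + neg_log_joint(mu - ei - ej)
                ) / (4 * h * h)
        L = np.linalg.cholesky(np.linalg.inv(H))
        if k == 1:
            Z = nodes[None, :]
            W = weights
        else:
            Z = np.array(np.meshgrid(nodes, nodes)).reshape(2, -1)
            W = np.outer(weights, weights).ravel()
        pts = mu[:, None] + L @ Z
        log_vals = np.array([-neg_log_joint(pts[:, i]) for i in range(pts.shape[1])])
        terms = log_vals + 0.5 * np.sum(Z**2, axis=0)
        m = terms.max()
        integral = abs(np.linalg.det(L)) * np.sum(W * np.exp(terms - m))
        total += -2.0 * (math.log(integral) + m)
    return total
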