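"""Deterministic calibration of the HADS phenotype generator defaults.

The generator builds each subscale score from a standard-normal latent trait
through 7 ordinal items: item propensity = latent + N(0, sigma_item), cut at
thresholds tau1 < tau2 < tau3 into {0, 1, 2, 3}, then summed (0-21).  This
script computes, by Gauss-Hermite quadrature (no Monte Carlo):

* per-subscale thresholds tau matching the target cumulative category
  proportions P(S <= 7), P(S <= 10), P(S <= 14);
* the latent correlation rho_z for which the *score-level* Pearson
  correlation between the two subscales equals its target (0.55), and the
  residual latent correlation rho_e after removing the shared age/sex
  couplings;
* the attenuation factor lambda = corr(score, latent) used to convert target
  lipid-score correlations into latent loadings.

Targets (population-cohort anchors): HADS-D: 81% <= 7, 11% mild (8-10),
6.5% moderate (11-14), 1.5% severe (>= 15); HADS-A: 65% / 20% / 12% / 3%;
score correlation 0.55.

Run:  python scripts/calibrate_phenotypes.py
The printed constants are frozen in lipidhads.synthetic_data.GeneratorConfig.
"""

import numpy as np
from scipy import optimize, stats

SIGMA_ITEM = 1.0
N_ITEMS = 7

# Cumulative targets at the standard HADS category boundaries.
TARGETS = {
    "hads_d": {7: 0.81, 10: 0.92, 14: 0.985},
    "hads_a": {7: 0.65, 10: 0.85, 14: 0.97},
}
TARGET_SCORE_CORR = 0.55

# Demographic couplings (standardized covariates entering the latent traits):
# anxiety ~ age (R^2 = 6%) and sex (3%); depression ~ age (R^2 = 1%).
AGE_TO_ANX = -0.245
SEX_TO_ANX = 0.17
AGE_TO_DEP = -0.10

_nodes, _weights = np.polynomial.hermite.hermgauss(80)
Z_NODES = np.sqrt(2.0) * _nodes
Z_WEIGHTS = _weights / np.sqrt(np.pi)


def item_pmf(z: np.ndarray, tau: np.ndarray, sigma: float = SIGMA_ITEM) -> np.ndarray:
    """P(item = 0..3 | latent = z); shape (len(z), 4)."""
    edges = stats.norm.cdf((np.asarray(tau)[None, :] - z[:, None]) / sigma)
    p = np.empty((z.size, 4))
    p[:, 0] = edges[:, 0]
    p[:, 1] = edges[:, 1] - edges[:, 0]
    p[:, 2] = edges[:, 2] - edges[:, 1]
    p[:, 3] = 1.0 - edges[:, 2]
    return p


def sum_pmf(p_item: np.ndarray) -> np.ndarray:
    """Distribution of the 7-item sum given z; shape (len(z), 22)."""
    out = np.zeros((p_item.shape[0], 1))
    out[:, 0] = 1.0
    for _ in range(N_ITEMS):
        new = np.zeros((p_item.shape[0], out.shape[1] + 3))
        for v in range(4):
            new[:, v : v + out.shape[1]] += out * p_item[:, [v]]
        out = new
    return out


def score_cdf(tau: np.ndarray) -> np.ndarray:
    """Marginal CDF of the subscale sum over the latent, F(0..21)."""
    pmf = sum_pmf(item_pmf(Z_NODES, tau))
    marginal = Z_WEIGHTS @ pmf
    return np.cumsum(marginal)


def fit_thresholds(targets: dict) -> np.ndarray:
    """Solve tau so that the score CDF hits the cumulative targets."""

    def unpack(theta):
        t1, g1, g2 = theta
        return np.array([t1, t1 + np.exp(g1), t1 + np.exp(g1) + np.exp(g2)])

    def loss(theta):
        F = score_cdf(unpack(theta))
        return [F[b] - v for b, v in sorted(targets.items())]

    sol = optimize.least_squares(loss, x0=[1.0, 0.0, 0.0], xtol=1e-14, ftol=1e-14)
    return unpack(sol.x)


def conditional_moments(tau: np.ndarray):
    """E[S|z], Var[S|z] on the quadrature grid."""
    p = item_pmf(Z_NODES, tau)
    vals = np.arange(4)
    m1 = p @ vals
    m2 = p @ vals**2
    return N_ITEMS * m1, N_ITEMS * (m2 - m1**2)


def score_moments(tau: np.ndarray):
    """Marginal mean, variance of S and corr(S, z)."""
    mean_z, var_z = conditional_moments(tau)
    mu = Z_WEIGHTS @ mean_z
    var = Z_WEIGHTS @ var_z + Z_WEIGHTS @ (mean_z - mu) ** 2
    cov_sz = Z_WEIGHTS @ (Z_NODES * mean_z)
    return mu, var, cov_sz / np.sqrt(var)


def score_correlation(tau_a: np.ndarray, tau_d: np.ndarray, rho: float) -> float:
    """corr(S_A, S_D) when the latents are bivariate normal with corr rho."""
    mean_a, _ = conditional_moments(tau_a)
    mean_d, _ = conditional_moments(tau_d)
    mu_a, var_a, _ = score_moments(tau_a)
    mu_d, var_d, _ = score_moments(tau_d)
    # E[m_a(z1) m_d(z2)], z2 = rho z1 + sqrt(1-rho^2) u, double quadrature.
    z2 = rho * Z_NODES[:, None] + np.sqrt(1 - rho**2) * Z_NODES[None, :]
    md_z2 = np.interp(z2, Z_NODES, mean_d)
    inner = (md_z2 * Z_WEIGHTS[None, :]).sum(axis=1)
    e_prod = Z_WEIGHTS @ (mean_a * inner)
    return (e_prod - mu_a * mu_d) / np.sqrt(var_a * var_d)


def main() -> None:
    tau = {}
    for scale, tgt in TARGETS.items():
        tau[scale] = fit_thresholds(tgt)
        F = score_cdf(tau[scale])
        print(f"{scale}: tau = {np.round(tau[scale], 6).tolist()}")
        for b, v in sorted(tgt.items()):
            print(f"   P(S <= {b:2d}) = {F[b]:.4f}  (target {v})")
        mu, var, lam = score_moments(tau[scale])
        print(f"   mean = {mu:.3f}, sd = {np.sqrt(var):.3f}, corr(S, z) = {lam:.4f}")

    rho_z = optimize.brentq(
        lambda r: score_correlation(tau["hads_a"], tau["hads_d"], r) - TARGET_SCORE_CORR,
        0.01, 0.99, xtol=1e-10,
    )
    shared = AGE_TO_ANX * AGE_TO_DEP
    rho_e = (rho_z - shared) / np.sqrt(
        (1 - AGE_TO_ANX**2 - SEX_TO_ANX**2) * (1 - AGE_TO_DEP**2)
    )
    print(f"\nlatent corr rho_z for score corr {TARGET_SCORE_CORR}: {rho_z:.6f}")
    print(f"residual latent corr rho_e (after age/sex couplings): {rho_e:.6f}")

    _, _, lam_d = score_moments(tau["hads_d"])
    print(f"lambda_d = corr(HADS-D score, depression latent) = {lam_d:.6f}")


if __name__ == "__main__":
    main()
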