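"""Shared test fixtures-in-code: independent oracles and scenario builders."""

import math

from mnph.bioheat import BloodProperties, TissueMaterial, TissueModel


def lrt_oracle(D, d_shell, M_d, K, eta, phi, tau_0, H_0, f, T):
    """Independent straight-line evaluation of the whole heating chain."""
    mu0 = 4e-7 * math.pi
    kB = 1.38e-23
    Vm = math.pi / 6 * D**3
    Vh = math.pi / 6 * (D + 2 * d_shell) ** 3
    xi = mu0 * M_d * Vm * H_0 / (kB * T)
    chi_i = mu0 * phi * M_d**2 * Vm / (3 * kB * T)
    if xi < 1e-4:
        slope = 1.0 - xi**2 / 15.0 + 2.0 * xi**4 / 315.0
    else:
        slope = (3 / xi) * (1 / math.tanh(xi) - 1 / xi)
    chi0 = chi_i * slope
    gamma = K * Vm / (kB * T)
    tauN = math.sqrt(math.pi) / 2 * tau_0 * math.exp(gamma) / math.sqrt(gamma)
    tauB = 3 * eta * Vh / (kB * T)
    tau = 1.0 / (1.0 / tauN + 1.0 / tauB)
    wt = 2 * math.pi * f * tau
    return math.pi * mu0 * chi0 * H_0**2 * f * wt / (1 + wt**2)


def uniform_model(**overrides):
    """Scenario with identical tumor/skin materials (no interface effects)."""
    mat = TissueMaterial(rho=1090.0, C_p=3421.0, k=0.563, omega_b=1.34e-2, Q_met=0.0)
    base = dict(
        tumor_radius=5e-3,
        skin_radius=15e-3,
        height=30e-3,
        tumor=mat,
        skin=mat,
        blood=BloodProperties(),
        Q_nano=0.0,
        h=0.0,
        convective_faces=(),
    )
    base.update(overrides)
    return TissueModel(**base)
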