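"""Single-site ITC isotherm simulation and fitting.

Models an isothermal titration calorimetry experiment with a single set
of independent sites in either titration orientation (protein in the
cell titrated with ligand, or the reverse). Internal units are fixed:
concentrations μM, volumes μL, injection heats μcal, ΔH cal/mol.

The injected-heat model follows standard instrument software: after each
injection the cell contents are diluted by (1 − dV/V0) (perfusion
approximation; an exact-displacement variant is available), the
cumulative binding heat is

    Q(i) = n · M_t(i) · ΔH · V0 · f_b(i)

and the observed injection heat includes the displaced-volume correction

    ΔQ(i) = Q(i) − Q(i−1) + (dV_i/V0) · (Q(i) + Q(i−1))/2 + offset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

#: Wiseman c-parameter range outside which a fit is poorly conditioned
C_PARAMETER_RANGE = (1.0, 1000.0)


class ITCError(ValueError):
    """Raised on invalid protocols, thermograms or failed fits."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ITCProtocol:
    """Cell/syringe composition and injection schedule of one experiment."""

    cell_uM: float
    syringe_uM: float
    injection_volumes_uL: Tuple[float, ...]
    cell_volume_uL: float = 200.0
    temperature_K: float = 298.15
    cell_species: str = "cell"
    syringe_species: str = "syringe"

    def __post_init__(self) -> None:
        if self.cell_uM <= 0 or self.syringe_uM <= 0:
            raise ITCError("concentrations must be positive")
        if self.cell_volume_uL <= 0:
            raise ITCError("cell volume must be positive")
        if not self.injection_volumes_uL or \
                any(v <= 0 for v in self.injection_volumes_uL):
            raise ITCError("injection volumes must be positive")
        object.__setattr__(self, "injection_volumes_uL",
                           tuple(float(v) for v in self.injection_volumes_uL))

    @classmethod
    def uniform(cls, cell_uM: float, syringe_uM: float,
                n_injections: int = 38, injection_uL: float = 1.0,
                **kwargs) -> "ITCProtocol":
        return cls(cell_uM, syringe_uM,
                   tuple([injection_uL] * n_injections), **kwargs)

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_uL)


@dataclass
class ITCThermogram:
    """Per-injection volumes and heats of one titration."""

    injection_volumes_uL: List[float]
    heats_ucal: List[float]

    def __post_init__(self) -> None:
        if len(self.injection_volumes_uL) != len(self.heats_ucal):
            raise ITCError("volumes and heats must have equal length")
        if not all(math.isfinite(h) for h in self.heats_ucal):
            raise ITCError("heats must be finite")

    def normalized_kcal_per_mol(self, protocol: ITCProtocol) -> np.ndarray:
        """Heats per mole of injectant, kcal/mol."""
        vols = np.asarray(self.injection_volumes_uL)
        moles = protocol.syringe_uM * 1e-6 * vols * 1e-6  # mol
        return np.asarray(self.heats_ucal) * 1e-6 / (moles * 1e3)


@dataclass
class SingleSiteFit:
    """Parameters of a single-set-of-sites binding model."""

    n: float
    kd_uM: float
    dh_cal_per_mol: float
    offset_ucal: float = 0.0
    residual_norm: float = 0.0
    stderr: dict = field(default_factory=dict)
    flags: tuple = ()

    def __post_init__(self) -> None:
        if self.kd_uM <= 0 or self.n <= 0:
            raise ITCError("n and Kd must be positive")


# ---------------------------------------------------------------------------
# equilibrium
# ---------------------------------------------------------------------------

def fraction_bound(p_total: float, l_total: float, kd: float) -> float:
    """Fraction of P bound at total concentrations P_t, L_t (single site).

    Closed-form root of the binding quadratic, evaluated in the
    cancellation-free form f_b = 2 L_t / (b + sqrt(b² − 4 P_t L_t)) with
    b = P_t + L_t + Kd.
    """
    if p_total <= 0 or l_total < 0 or kd <= 0:
        raise ValueError("require P_t > 0, L_t >= 0, Kd > 0")
    if l_total == 0:
        return 0.0
    b = p_total + l_total + kd
    disc = b * b - 4.0 * p_total * l_total
    fb = 2.0 * l_total / (b + math.sqrt(max(disc, 0.0)))
    return min(fb, 1.0)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _cumulative_heats(protocol: ITCProtocol, n: float, kd_uM: float,
                      dh: float, dilution: str) -> np.ndarray:
    """Cumulative binding heat Q(i) in μcal after each injection."""
    v0 = protocol.cell_volume_uL
    m = protocol.cell_uM
    x = 0.0
    q = np.empty(protocol.n_injections)
    for i, dv in enumerate(protocol.injection_volumes_uL):
        if dilution == "perfusion":
            factor = 1.0 - dv / v0
            m *= factor
            x = x * factor + protocol.syringe_uM * dv / v0
        elif dilution == "exact":
            factor = v0 / (v0 + dv)
            m *= factor
            x = (x * v0 + protocol.syringe_uM * dv) / (v0 + dv)
        else:
            raise ITCError(f"unknown dilution model {dilution!r}")
        fb = fraction_bound(n * m, x, kd_uM)
        # μM · μL · cal/mol = 1e-6 μcal
        q[i] = n * m * v0 * dh * fb * 1e-6
    return q


def injection_heats(protocol: ITCProtocol, fit: SingleSiteFit,
                    dilution: str = "perfusion") -> np.ndarray:
    """Noise-free injection heats ΔQ(i) in μcal, including the
    displaced-volume correction and baseline offset."""
    q = _cumulative_heats(protocol, fit.n, fit.kd_uM, fit.dh_cal_per_mol,
                          dilution)
    v0 = protocol.cell_volume_uL
    dq = np.empty_like(q)
    prev = 0.0
    for i, dv in enumerate(protocol.injection_volumes_uL):
        dq[i] = q[i] - prev + (dv / v0) * (q[i] + prev) / 2.0 + fit.offset_ucal
        prev = q[i]
    return dq


def peak_noise_sigma(protocol: ITCProtocol, truth: SingleSiteFit,
                     fraction: float = 0.02,
                     dilution: str = "perfusion") -> float:
    """Noise σ in μcal equal to a fraction of the largest injection heat."""
    clean = injection_heats(protocol, replace(truth, offset_ucal=0.0),
                            dilution)
    return fraction * float(np.max(np.abs(clean)))


def simulate_itc(protocol: ITCProtocol, truth: SingleSiteFit,
                 noise_sigma_ucal: float = 0.0, seed: int = 0,
                 dilution: str = "perfusion") -> ITCThermogram:
    """Simulate a thermogram under the single-site model plus Gaussian noise."""
    if noise_sigma_ucal < 0:
        raise ITCError("noise sigma must be non-negative")
    dq = injection_heats(protocol, truth, dilution)
    if noise_sigma_ucal > 0:
        rng = np.random.default_rng(seed)
        dq = dq + rng.normal(0.0, noise_sigma_ucal, size=dq.shape)
    return ITCThermogram(list(protocol.injection_volumes_uL),
                         [float(h) for h in dq])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_itc(thermogram: ITCThermogram, protocol: ITCProtocol,
            discard_first: bool = False,
            dilution: str = "perfusion") -> SingleSiteFit:
    """Nonlinear least-squares fit of (n, Kd, ΔH, offset) to a thermogram.

    Standard errors are estimated from the Jacobian at the optimum. A
    Wiseman c-parameter (n·M_cell/Kd) outside [1, 1000] produces a
    logged warning; a Kd at the search bound flags the fit.
    """
    if len(thermogram.heats_ucal) < 6:
        raise ITCError("at least 6 injections are required for a fit")
    if len(thermogram.heats_ucal) != protocol.n_injections:
        raise ITCError("thermogram and protocol injection counts differ")

    y = np.asarray(thermogram.heats_ucal, dtype=float)
    weights = np.ones_like(y)
    if discard_first:
        weights[0] = 0.0

    # initial guesses: total heat fixes ΔH at n=1; offset from the tail
    offset0 = float(np.mean(y[-3:]))
    total_q = float(np.sum(y - offset0))
    sites0 = protocol.cell_uM * protocol.cell_volume_uL * 1e-6  # μmol-scale
    dh0 = total_q / sites0 if sites0 else -1000.0
    if abs(dh0) < 10.0:
        dh0 = -1000.0
    kd0 = max(protocol.cell_uM / 2.0, 1.0)

    log_kd_bounds = (-3.0, 7.0)

    def residual(x: np.ndarray) -> np.ndarray:
        n, log_kd, dh, offset = x
        model = injection_heats(
            protocol, SingleSiteFit(n, 10.0 ** log_kd, dh, offset), dilution)
        return (model - y) * weights

    x0 = np.array([1.0, np.log10(kd0), dh0, offset0])
    result = least_squares(
        residual, x0,
        bounds=([1e-3, log_kd_bounds[0], -np.inf, -np.inf],
                [1e3, log_kd_bounds[1], np.inf, np.inf]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=50000)
    if not result.success:
        raise ITCError(f"ITC fit did not converge: {result.message}")

    n, log_kd, dh, offset = result.x
    flags: List[str] = []
    if log_kd <= log_kd_bounds[0] + 1e-6 or log_kd >= log_kd_bounds[1] - 1e-6:
        flags.append("kd_at_bound")
        logger.warning("fitted Kd is at the search bound (log10 Kd = %.2f)",
                       log_kd)

    stderr = {}
    try:
        jac = result.jac
        dof = max(len(y) - len(result.x), 1)
        cov = np.linalg.inv(jac.T @ jac) * 2.0 * result.cost / dof
        se = np.sqrt(np.diag(cov))
        kd = 10.0 ** log_kd
        stderr = {"n": float(se[0]),
                  "kd_uM": float(se[1] * kd * math.log(10.0)),
                  "dh_cal_per_mol": float(se[2]),
                  "offset_ucal": float(se[3])}
    except np.linalg.LinAlgError:
        flags.append("singular_covariance")

    c = n * protocol.cell_uM / (10.0 ** log_kd)
    if not (C_PARAMETER_RANGE[0] <= c <= C_PARAMETER_RANGE[1]):
        logger.warning("Wiseman c-parameter %.2f outside %s; Kd estimate "
                       "may be poorly determined", c, C_PARAMETER_RANGE)

    return SingleSiteFit(float(n), float(10.0 ** log_kd), float(dh),
                         float(offset), float(np.linalg.norm(result.fun)),
                         stderr, tuple(flags))


# ---------------------------------------------------------------------------
# thermogram I/O
# ---------------------------------------------------------------------------

def read_thermogram(path: str | Path) -> ITCThermogram:
    """Read a TSV thermogram: injection, dV_uL, heat_ucal."""
    vols: List[float] = []
    heats: List[float] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ITCError(f"{path}: line {lineno}: expected 3 columns")
        try:
            vols.append(float(fields[1]))
            heats.append(float(fields[2]))
        except ValueError:
            raise ITCError(f"{path}: line {lineno}: non-numeric value") from None
    return ITCThermogram(vols, heats)


def write_thermogram(thermogram: ITCThermogram, path: str | Path) -> None:
    lines = ["# injection\tdV_uL\theat_ucal"]
    for i, (dv, h) in enumerate(zip(thermogram.injection_volumes_uL,
                                    thermogram.heats_ucal), start=1):
        lines.append(f"{i}\t{dv:.3f}\t{h:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
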