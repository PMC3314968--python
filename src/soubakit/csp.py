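"""Chemical shift perturbation (CSP) analysis of HSQC titrations.

Implements the standard amide CSP combination

    Δδ = sqrt(ΔδH² + (ΔδN/5)²)

with the convention that prolines and otherwise unobserved residues are
assigned Δδ = 0 ppm and flagged, interface mapping by a Δδ threshold
(default 0.2 ppm), contiguous-region detection, and a global fast-exchange
Kd fit across a titration series (shared Kd, per-residue amplitude,
single-site quadratic fraction bound).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, NamedTuple, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .binding import fraction_bound

logger = logging.getLogger(__name__)

#: weight dividing the nitrogen shift change in the CSP combination
NITROGEN_SCALE = 5.0
#: operative interface cutoff, ppm
DEFAULT_INTERFACE_THRESHOLD = 0.2
#: residues whose largest shift change is below this (ppm) are treated as
#: unresponsive and excluded from the titration fit
DEFAULT_MIN_AMPLITUDE = 0.01

_SPARKY_RE = re.compile(r"^[A-Za-z]{1,3}(\d+)N-?H$")


class PeakListError(ValueError):
    """Raised on malformed peak-list tables."""


class TitrationError(ValueError):
    """Raised on invalid titration series or failed Kd fits."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PeakList:
    """Assigned amide peaks of one spectrum: residue -> (δH, δN) in ppm."""

    shifts: Dict[int, Tuple[float, float]]
    label: str = ""

    def __post_init__(self) -> None:
        for res, (dh, dn) in self.shifts.items():
            if not (math.isfinite(dh) and math.isfinite(dn)):
                raise PeakListError(f"non-finite shift for residue {res}")
            if not (5.0 <= dh <= 12.0) or not (100.0 <= dn <= 135.0):
                logger.warning(
                    "peak list %r: residue %d shifts (%.2f, %.2f) outside "
                    "typical amide ranges", self.label, res, dh, dn)

    def residues(self) -> List[int]:
        return sorted(self.shifts)


@dataclass
class CSPProfile:
    """Per-residue Δδ in ppm; flagged residues (prolines/unobserved) are 0."""

    values: Dict[int, float]
    flagged: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.values.values()):
            raise ValueError("CSP values must be non-negative")

    def residues(self) -> List[int]:
        return sorted(self.values)


@dataclass
class TitrationSeries:
    """Ordered titration points (total ligand μM, peak list); first is apo."""

    protein_uM: float
    points: List[Tuple[float, PeakList]]

    def __post_init__(self) -> None:
        if self.protein_uM <= 0:
            raise TitrationError("protein concentration must be positive")
        concs = [c for c, _ in self.points]
        if not concs or concs[0] != 0.0:
            raise TitrationError("first titration point must be apo (0 μM)")
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise TitrationError("ligand concentrations must be strictly increasing")


class TitrationFit(NamedTuple):
    kd_uM: float
    ddmax: Dict[int, float]
    residual_norm: float


# ---------------------------------------------------------------------------
# peak-list I/O
# ---------------------------------------------------------------------------

def _parse_residue(token: str, lineno: int) -> int:
    if token.lstrip("-").isdigit():
        return int(token)
    m = _SPARKY_RE.match(token)
    if m:
        return int(m.group(1))
    raise PeakListError(
        f"line {lineno}: cannot parse residue id {token!r} "
        "(expected an integer or a Sparky-style assignment like 'L44N-H')")


def read_peaklist(path: str | Path, label: str | None = None) -> PeakList:
    """Read a whitespace/TSV peak list with columns residue, δH, δN.

    Lines starting with ``#`` are comments. Duplicate residues are an
    error reported with the line number.
    """
    path = Path(path)
    shifts: Dict[int, Tuple[float, float]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise PeakListError(
                f"{path}: line {lineno}: expected 3 columns "
                f"(residue, dH_ppm, dN_ppm), got {len(fields)}")
        res = _parse_residue(fields[0], lineno)
        try:
            dh, dn = float(fields[1]), float(fields[2])
        except ValueError:
            raise PeakListError(
                f"{path}: line {lineno}: non-numeric shift in {fields[1:3]}"
            ) from None
        if res in shifts:
            raise PeakListError(
                f"{path}: line {lineno}: duplicate residue {res}")
        shifts[res] = (dh, dn)
    return PeakList(shifts, label=label if label is not None else path.stem)


def write_csp_profile(profile: CSPProfile, path: str | Path) -> None:
    """Export a CSP profile as TSV: residue, csp_ppm, flag."""
    lines = ["# residue\tcsp_ppm\tflag"]
    for res in profile.residues():
        flag = "flagged" if res in profile.flagged else "-"
        lines.append(f"{res}\t{profile.values[res]:.4f}\t{flag}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# CSP computation and interface mapping
# ---------------------------------------------------------------------------

def csp_value(delta_h: float, delta_n: float) -> float:
    """Weighted amide CSP: sqrt(ΔδH² + (ΔδN/5)²)."""
    return math.sqrt(delta_h ** 2 + (delta_n / NITROGEN_SCALE) ** 2)


def compute_csp(apo: PeakList, bound: PeakList) -> CSPProfile:
    """Per-residue CSP between two assigned peak lists.

    Residues present in only one list (prolines, exchange-broadened or
    unassigned peaks) are assigned Δδ = 0 and flagged.
    """
    shared = set(apo.shifts) & set(bound.shifts)
    if not shared:
        raise PeakListError("peak lists share no residues")
    values: Dict[int, float] = {}
    flagged = set()
    for res in set(apo.shifts) | set(bound.shifts):
        if res in shared:
            dh = bound.shifts[res][0] - apo.shifts[res][0]
            dn = bound.shifts[res][1] - apo.shifts[res][1]
            values[res] = csp_value(dh, dn)
        else:
            values[res] = 0.0
            flagged.add(res)
    return CSPProfile(values, frozenset(flagged))


def map_interface_residues(
    profile: CSPProfile, threshold: float = DEFAULT_INTERFACE_THRESHOLD
) -> List[int]:
    """Residues with Δδ above the threshold; flagged residues excluded."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return [r for r in profile.residues()
            if r not in profile.flagged and profile.values[r] > threshold]


def contiguous_regions(
    residues: Sequence[int], max_gap: int = 0
) -> List[Tuple[int, int]]:
    """Maximal runs of residues whose successive gaps are <= max_gap + 1."""
    if list(residues) != sorted(residues):
        raise ValueError("residues must be sorted ascending")
    regions: List[Tuple[int, int]] = []
    for res in residues:
        if regions and res - regions[-1][1] <= max_gap + 1:
            regions[-1] = (regions[-1][0], res)
        else:
            regions.append((res, res))
    return regions


# ---------------------------------------------------------------------------
# fast-exchange Kd fitting
# ---------------------------------------------------------------------------

def _observed_csps(series: TitrationSeries) -> Tuple[List[int], np.ndarray, np.ndarray]:
    """Residues observed at every point, ligand concs and CSP matrix."""
    apo = series.points[0][1]
    ligand = np.array([c for c, _ in series.points[1:]], dtype=float)
    profiles = [compute_csp(apo, pl) for _, pl in series.points[1:]]
    good = sorted(
        r for r in apo.shifts
        if all(r in p.values and r not in p.flagged for p in profiles)
    )
    mat = np.array([[p.values[r] for r in good] for p in profiles])
    return good, ligand, mat


def fit_titration_kd(
    series: TitrationSeries,
    min_amplitude: float = DEFAULT_MIN_AMPLITUDE,
) -> TitrationFit:
    """Global fast-exchange fit of a titration series.

    The observed CSP of residue *j* at total ligand L is modelled as
    Δδ_obs = Δδ_max(j) · f_b(P_t, L, Kd) with a single shared Kd and the
    single-site quadratic fraction bound. The fit is trust-region least
    squares over (log10 Kd, Δδ_max...); Kd is initialised at the ligand
    concentration of half-maximal mean shift.
    """
    if len(series.points) < 3:
        raise TitrationError("at least 3 titration points are required")
    residues, ligand, csps = _observed_csps(series)
    responsive = [j for j, r in enumerate(residues)
                  if csps[:, j].max() >= min_amplitude]
    if not responsive:
        raise TitrationError("no responsive residues (all CSPs ~ 0)")
    resp_res = [residues[j] for j in responsive]
    y = csps[:, responsive]
    p_t = series.protein_uM

    mean_curve = y.mean(axis=1)
    half = 0.5 * mean_curve.max()
    above = np.nonzero(mean_curve >= half)[0]
    kd0 = float(ligand[above[0]]) if len(above) else float(ligand[-1])
    kd0 = max(kd0, 1.0)
    fb0 = np.array([fraction_bound(p_t, L, kd0) for L in ligand])
    amp0 = y.max(axis=0) / max(fb0.max(), 1e-9)

    def residual(x: np.ndarray) -> np.ndarray:
        kd = 10.0 ** x[0]
        amps = x[1:]
        fb = np.array([fraction_bound(p_t, L, kd) for L in ligand])
        return (fb[:, None] * amps[None, :] - y).ravel()

    x0 = np.concatenate([[np.log10(kd0)], amp0])
    result = least_squares(residual, x0, method="trf",
                           xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if not result.success:
        raise TitrationError(
            f"titration fit did not converge: {result.message} "
            f"(status {result.status}, cost {result.cost:.3g})")
    kd = float(10.0 ** result.x[0])
    ddmax = {r: float(a) for r, a in zip(resp_res, result.x[1:])}
    return TitrationFit(kd, ddmax, float(np.linalg.norm(result.fun)))
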