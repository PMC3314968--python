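"""Paramagnetic relaxation enhancement (PRE) prediction and comparison.

A nitroxide spin label conjugated to an engineered cysteine broadens the
amide resonances of nearby residues; the observable is the intensity
ratio between the paramagnetic spectrum and a diamagnetic control in
which the label has been reduced (e.g. by ascorbic acid). This module
places a single pseudo-label atom on a docked ubiquitin copy, predicts
per-residue intensity ratios on the receptor with the Solomon–
Bloembergen r⁻⁶ transverse rate

    Γ₂ = K_SB · r⁻⁶ · (4τc + 3τc / (1 + ωH²τc²))
    I_para/I_dia = R₂ · exp(−Γ₂ t) / (R₂ + Γ₂)

and compares predicted with observed attenuation profiles by residuals
and by the Jaccard overlap of their significant-attenuation regions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from .csp import contiguous_regions
from .docking import DockedModel
from .structlib import Structure

logger = logging.getLogger(__name__)

#: Solomon–Bloembergen dipolar constant for an amide ¹H and a nitroxide
#: electron, in Å⁶·s⁻² (1.23e-32 cm⁶·s⁻²)
K_SB_DEFAULT = 1.23e16
#: distance from Cβ to the pseudo-label point along the Cα→Cβ direction, Å
LABEL_OFFSET = 6.0
#: intensity-ratio threshold below which attenuation is significant
DEFAULT_RATIO_THRESHOLD = 0.7
#: minimum run length (residues) for a significant region
DEFAULT_MIN_RUN = 2


class SpinLabelError(ValueError):
    """Raised when a spin-label site cannot be constructed."""


class PREError(ValueError):
    """Raised on invalid PRE profiles or insufficient overlap."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PREParams:
    """Relaxation parameters of the PRE prediction.

    tau_c_s        rotational correlation time of the complex (s)
    r2_s           diamagnetic transverse relaxation rate (s⁻¹)
    total_time_s   effective transverse evolution time (s)
    h_freq_mhz     ¹H spectrometer frequency (MHz)
    k_sb           dipolar constant (Å⁶ s⁻²); 0 models the reduced label
    """

    tau_c_s: float = 10e-9
    r2_s: float = 20.0
    total_time_s: float = 0.010
    h_freq_mhz: float = 700.0
    k_sb: float = K_SB_DEFAULT


@dataclass(frozen=True)
class SpinLabelSite:
    copy_id: str
    residue: int
    position: np.ndarray


@dataclass
class PREProfile:
    """Observed intensity ratios I_para/I_dia per residue."""

    values: Dict[int, float]
    flagged: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.values.values()):
            raise PREError("intensity ratios must be non-negative")

    def residues(self) -> List[int]:
        return sorted(self.values)


@dataclass
class PREPrediction:
    """Predicted intensity ratios with the parameters that produced them."""

    values: Dict[int, float]
    params: PREParams
    site: SpinLabelSite
    flagged: frozenset = field(default_factory=frozenset)

    def residues(self) -> List[int]:
        return sorted(self.values)


# ---------------------------------------------------------------------------
# spin-label placement
# ---------------------------------------------------------------------------

def attach_spin_label(model: DockedModel, copy_id: str, residue: int,
                      offset: float = LABEL_OFFSET) -> SpinLabelSite:
    """Place a pseudo-label on a ubiquitin copy's residue.

    The nitroxide is approximated by a single point at Cβ + offset along
    the Cα→Cβ direction (for glycine, Cα + offset along the local
    backbone normal); no rotamer ensemble is modelled.
    """
    structure = model.structure
    if copy_id not in structure.chains():
        raise SpinLabelError(f"no chain {copy_id!r} in the model")
    try:
        ca = structure.atom(copy_id, residue, "CA").coords
    except KeyError:
        raise SpinLabelError(
            f"residue {residue} of copy {copy_id} is missing") from None
    if structure.has_atom(copy_id, residue, "CB"):
        cb = structure.atom(copy_id, residue, "CB").coords
        direction = cb - ca
        direction /= np.linalg.norm(direction)
        pos = cb + offset * direction
    else:
        n = structure.atom(copy_id, residue, "N").coords
        c = structure.atom(copy_id, residue, "C").coords
        normal = np.cross(n - ca, c - ca)
        norm = np.linalg.norm(normal)
        if norm < 1e-9:
            raise SpinLabelError(
                f"degenerate backbone geometry at {copy_id}/{residue}")
        pos = ca + offset * normal / norm
    return SpinLabelSite(copy_id, residue, pos)


# ---------------------------------------------------------------------------
# attenuation prediction
# ---------------------------------------------------------------------------

def gamma2(r: float, params: PREParams) -> float:
    """Paramagnetic transverse rate at label distance r (Å), s⁻¹."""
    if r <= 0:
        return math.inf
    omega = 2.0 * math.pi * params.h_freq_mhz * 1e6
    tau = params.tau_c_s
    spectral = 4.0 * tau + 3.0 * tau / (1.0 + (omega * tau) ** 2)
    return params.k_sb / r ** 6 * spectral


def intensity_ratio(r: float, params: PREParams) -> float:
    """Predicted I_para/I_dia at label distance r (Å)."""
    g = gamma2(r, params)
    if math.isinf(g):
        return 0.0
    return params.r2_s * math.exp(-g * params.total_time_s) / (params.r2_s + g)


def _amide_position(structure: Structure, chain: str, resnum: int,
                    prev_resnum: int | None) -> np.ndarray | None:
    """Amide ¹H position: H if present, else reconstructed, else N."""
    if structure.has_atom(chain, resnum, "H"):
        return structure.atom(chain, resnum, "H").coords
    if not structure.has_atom(chain, resnum, "N"):
        return None
    n = structure.atom(chain, resnum, "N").coords
    if (prev_resnum is not None
            and structure.has_atom(chain, resnum, "CA")
            and structure.has_atom(chain, prev_resnum, "C")):
        ca = structure.atom(chain, resnum, "CA").coords
        c_prev = structure.atom(chain, prev_resnum, "C").coords
        v1 = n - ca
        v2 = n - c_prev
        norm1, norm2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if norm1 > 1e-9 and norm2 > 1e-9:
            bisector = v1 / norm1 + v2 / norm2
            norm_b = np.linalg.norm(bisector)
            if norm_b > 1e-9:
                return n + 0.98 * bisector / norm_b
    logger.debug("falling back to N position for %s/%d", chain, resnum)
    return n


def predict_attenuation(model: DockedModel, site: SpinLabelSite,
                        params: PREParams | None = None) -> PREPrediction:
    """Predicted intensity ratios for every receptor residue."""
    params = params or PREParams()
    values: Dict[int, float] = {}
    flagged = set()
    for chain in model.receptor.chains():
        nums = model.receptor.residue_numbers(chain)
        prev = None
        for resnum in nums:
            if model.receptor.residue_name(chain, resnum) == "PRO":
                values[resnum] = 1.0
                flagged.add(resnum)  # no amide proton
                prev = resnum
                continue
            amide = _amide_position(model.receptor, chain, resnum, prev)
            if amide is None:
                values[resnum] = 1.0
                flagged.add(resnum)
            else:
                r = float(np.linalg.norm(amide - site.position))
                values[resnum] = intensity_ratio(r, params)
            prev = resnum
    return PREPrediction(values, params, site, frozenset(flagged))


# ---------------------------------------------------------------------------
# region calls and comparison
# ---------------------------------------------------------------------------

def significant_regions(profile: PREProfile | PREPrediction,
                        threshold: float = DEFAULT_RATIO_THRESHOLD,
                        min_run: int = DEFAULT_MIN_RUN
                        ) -> List[Tuple[int, int]]:
    """Contiguous runs of >= min_run residues with ratio below threshold."""
    if threshold <= 0 or min_run < 1:
        raise ValueError("threshold must be positive and min_run >= 1")
    attenuated = [r for r in profile.residues()
                  if r not in profile.flagged and profile.values[r] < threshold]
    return [(a, b) for a, b in contiguous_regions(attenuated, max_gap=0)
            if b - a + 1 >= min_run]


def _region_residues(regions: List[Tuple[int, int]]) -> frozenset:
    out = set()
    for a, b in regions:
        out.update(range(a, b + 1))
    return frozenset(out)


def compare_pre(observed: PREProfile, predicted: PREPrediction,
                threshold: float = DEFAULT_RATIO_THRESHOLD,
                min_run: int = DEFAULT_MIN_RUN
                ) -> Tuple[Dict[int, float], float]:
    """Residuals (observed − predicted) and region-agreement Jaccard index.

    The Jaccard index compares the residue sets covered by the
    significant-attenuation regions of the two profiles, both restricted
    to residues present in both. Two empty region sets agree (index 1).
    """
    shared = sorted((set(observed.values) - observed.flagged)
                    & (set(predicted.values) - predicted.flagged))
    if len(shared) < 10:
        raise PREError(
            f"only {len(shared)} shared residues; at least 10 required")
    residuals = {r: observed.values[r] - predicted.values[r] for r in shared}

    obs_shared = PREProfile({r: observed.values[r] for r in shared})
    pred_shared = PREProfile({r: predicted.values[r] for r in shared})
    obs_set = _region_residues(significant_regions(obs_shared, threshold, min_run))
    pred_set = _region_residues(significant_regions(pred_shared, threshold, min_run))
    union = obs_set | pred_set
    jaccard = 1.0 if not union else len(obs_set & pred_set) / len(union)
    return residuals, jaccard


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_pre_profile(path: str | Path) -> PREProfile:
    """Read an observed PRE table: residue, I_ratio (whitespace/TSV)."""
    values: Dict[int, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 2:
            raise PREError(f"{path}: line {lineno}: expected 2 columns")
        try:
            res, ratio = int(fields[0]), float(fields[1])
        except ValueError:
            raise PREError(f"{path}: line {lineno}: non-numeric value") from None
        if res in values:
            raise PREError(f"{path}: line {lineno}: duplicate residue {res}")
        values[res] = ratio
    return PREProfile(values)


def write_pre_profile(profile: PREProfile | PREPrediction,
                      path: str | Path) -> None:
    lines = ["# residue\tI_ratio"]
    for res in profile.residues():
        lines.append(f"{res}\t{profile.values[res]:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")
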