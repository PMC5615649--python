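"""Normalized mass/volume/density bookkeeping for multi-constituent tissue.

The vessel wall is treated as a constrained mixture: every constituent
(elastin, ground matrix, collagen fiber families) is present at each material
point and deforms with the tissue.  Mass turnover changes a constituent's
normalized mass ``m_hat = m(tau)/m(0)``; how that mass change translates into
a *volume* change depends on the deposition rule:

* **CCD** (constant constituent density): volume grows with mass, so the
  normalized constituent volume change equals ``m_hat``.
* **CCV** (constant constituent volume): mass is packed into a fixed volume,
  so the constituent volume change is identically 1 and the constituent's
  density rises instead.

The normalized tissue volume change is the initial-volume-fraction-weighted
sum of the constituent volume changes,

    v_hat = sum_{CCD} m_hat_z * phi_z(0) + sum_{CCV} phi_z(0),

which feeds the growth kinematics, while normalized partial densities
``rho_hat_z = m_hat_z / v_hat`` weight each constituent's strain energy.

Volume fractions are defined and normalized per vessel layer (media,
adventitia); partial-density changes are always derived on demand and never
stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DepositionRule",
    "ConstituentState",
    "MixtureComposition",
    "constituent_volume_change",
    "tissue_volume_change",
    "partial_density_change",
    "volume_change_arrays",
]

#: tolerance on the volume-fraction closure sum
_FRACTION_TOL = 1e-12


class DepositionRule(str, Enum):
    """How added constituent mass occupies space."""

    CCD = "CCD"  #: constant constituent density — volume grows with mass
    CCV = "CCV"  #: constant constituent volume — density grows with mass


@dataclass
class ConstituentState:
    """One constituent of the mixture at a material point.

    Parameters
    ----------
    name:
        Identifier, e.g. ``"elastin"``, ``"ground"``, ``"collagen_1"``.
    rule:
        Deposition rule governing how mass change maps to volume change.
    phi0:
        Initial volume fraction of the constituent within its layer.
    m_hat:
        Normalized mass ``m(tau)/m(0)`` (1.0 at the reference time).
    """

    name: str
    rule: DepositionRule
    phi0: float
    m_hat: float = 1.0

    def __post_init__(self) -> None:
        self.rule = DepositionRule(self.rule)
        if not 0.0 <= self.phi0 <= 1.0:
            raise ValueError(f"phi0 must lie in [0, 1], got {self.phi0}")
        if self.m_hat < 0.0:
            raise ValueError(f"m_hat must be non-negative, got {self.m_hat}")

    @property
    def v_hat(self) -> float:
        """Normalized constituent volume change (m_hat for CCD, 1 for CCV)."""
        return constituent_volume_change(self)


@dataclass
class MixtureComposition:
    """Ordered collection of constituents whose initial fractions close to 1."""

    constituents: list[ConstituentState] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.constituents:
            total = sum(c.phi0 for c in self.constituents)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"initial volume fractions must sum to 1, got {total!r}"
                )

    def __iter__(self):
        return iter(self.constituents)

    def __len__(self) -> int:
        return len(self.constituents)

    def __getitem__(self, key):
        if isinstance(key, str):
            for c in self.constituents:
                if c.name == key:
                    return c
            raise KeyError(key)
        return self.constituents[key]

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.constituents]


def constituent_volume_change(c: ConstituentState) -> float:
    """Normalized volume change of a single constituent.

    Returns ``m_hat`` under CCD deposition and exactly 1.0 under CCV.
    """
    if c.m_hat < 0.0:
        raise ValueError(f"m_hat must be non-negative, got {c.m_hat}")
    if c.rule is DepositionRule.CCD:
        return float(c.m_hat)
    return 1.0


def tissue_volume_change(mix: MixtureComposition | Sequence[ConstituentState]) -> float:
    """Normalized tissue volume change of a multi-constituent mixture.

    ``v_hat = sum_{CCD} m_hat_z phi_z(0) + sum_{CCV} phi_z(0)``; the initial
    volume fractions must close to 1 (checked to 1e-12 on top of the
    construction-time check, so ad-hoc sequences are validated too).
    """
    constituents = list(mix)
    if not constituents:
        raise ValueError("cannot compute the volume change of an empty mixture")
    total_phi = sum(c.phi0 for c in constituents)
    if abs(total_phi - 1.0) > 1e-9:
        raise ValueError(f"volume fractions must sum to 1, got {total_phi!r}")
    v_hat = 0.0
    for c in constituents:
        v_hat += constituent_volume_change(c) * c.phi0
    if v_hat <= 0.0:
        raise ValueError(f"non-positive tissue volume change v_hat={v_hat}")
    return float(v_hat)


def partial_density_change(m_hat: float, v_hat: float):
    """Normalized partial density ``rho_hat = m_hat / v_hat``.

    The partial density is the constituent mass per *tissue* volume; with the
    true constituent density constant, its normalized change is forced to be
    the ratio of normalized mass to normalized tissue volume.  Accepts
    array-valued ``m_hat``.
    """
    if np.any(np.asarray(v_hat) <= 0.0):
        raise ValueError(f"v_hat must be positive, got {v_hat}")
    return m_hat / v_hat


def volume_change_arrays(
    phi0: np.ndarray,
    m_hat: np.ndarray,
    is_ccd: np.ndarray,
) -> np.ndarray:
    """Vectorized tissue volume change over arrays of constituents.

    Parameters
    ----------
    phi0 : (..., n_constituents) initial volume fractions, closing to 1.
    m_hat : (..., n_constituents) normalized masses.
    is_ccd : (n_constituents,) boolean mask of CCD-deposited constituents.

    Returns the tissue volume change with shape ``(...,)``.  Used by the
    vessel solver where per-point constituent masses are stored as arrays.
    """
    phi0 = np.asarray(phi0, dtype=float)
    m_hat = np.asarray(m_hat, dtype=float)
    is_ccd = np.asarray(is_ccd, dtype=bool)
    closure = phi0.sum(axis=-1)
    if not np.allclose(closure, 1.0, atol=1e-9):
        raise ValueError("volume fractions must sum to 1 along the last axis")
    v_c = np.where(is_ccd, m_hat, 1.0)
    return np.sum(v_c * phi0, axis=-1)
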