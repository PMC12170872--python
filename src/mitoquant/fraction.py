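"""Subcellular-fractionation algebra for membrane-associated protein splits.

Immunoblot band intensities from a fractionation experiment (cytosol, pure
mitochondria, proteinase-K-treated pure mitochondria) are converted into the
percentage of the protein localised to mitochondria and, within the outer
mitochondrial membrane, the split between the PK-protected (inner-leaflet)
and PK-digestible (outer-leaflet) pools.

Two correction factors enter the percentages:

* ``K_pl`` — purification loss, derived from the change of an IMS marker
  (cytochrome C) between crude and pure mitochondrial fractions.
* ``K_dm`` — damaged mitochondria, derived from the change of an embedded
  OMM marker (VDAC1) with and without PK treatment.

Each band amount is the blot intensity scaled by a loading dilution factor
``D1`` and a fraction-compensation factor ``D2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "FractionSheet",
    "FractionResult",
    "scale_band",
    "pct_mito",
    "pct_leaflet",
    "k_pl_from_cytc",
    "k_dm_from_vdac",
]


class NoSignalError(ValueError):
    """Raised when all relevant band intensities are zero ("no_signal")."""


@dataclass
class FractionSheet:
    """Band intensities and correction factors for one fractionation run.

    ``I_blot`` maps lane name -> raw intensity; ``D1`` and ``D2`` map lane
    name -> scaling factor (defaulting to 1 for missing lanes). Expected
    lane names: ``cyto``, ``p_mito``, ``p_mito_PK``.
    """

    I_blot: dict[str, float]
    D1: dict[str, float] = field(default_factory=dict)
    D2: dict[str, float] = field(default_factory=dict)
    K_pl: float = 1.0
    K_dm: float = 1.0

    def __post_init__(self) -> None:
        for name, I in self.I_blot.items():
            if I < 0:
                raise ValueError(f"band intensity for {name!r} must be >= 0")
        for factors in (self.D1, self.D2):
            for name, d in factors.items():
                if d <= 0:
                    raise ValueError(f"scaling factor for {name!r} must be > 0")
        if self.K_pl <= 0 or self.K_dm <= 0:
            raise ValueError("K_pl and K_dm must be > 0")

    def amount(self, lane: str) -> float:
        """Scaled band amount ``I_blot * D1 * D2`` for one lane."""
        return scale_band(
            self.I_blot[lane], self.D1.get(lane, 1.0), self.D2.get(lane, 1.0)
        )


@dataclass
class FractionResult:
    pct_p_mito: float | None = None
    pct_cyto: float | None = None
    pct_inner_leaflet: float | None = None
    pct_outer_leaflet: float | None = None
    clamped: bool = False
    warnings: list[str] = field(default_factory=list)


def scale_band(I_blot: float, D1: float, D2: float) -> float:
    """Scaled band amount: intensity x loading dilution x fraction compensation."""
    if I_blot < 0:
        raise ValueError("I_blot must be >= 0")
    if D1 <= 0 or D2 <= 0:
        raise ValueError("D factors must be > 0")
    return I_blot * D1 * D2


def _clamp_pct(value: float) -> tuple[float, bool]:
    if 0.0 <= value <= 100.0:
        return value, False
    return min(max(value, 0.0), 100.0), True


def pct_mito(sheet: FractionSheet) -> FractionResult:
    """Mitochondrial vs cytosolic split of the protein.

    pct_p_mito = A_mito / (A_mito + A_cyto) * K_pl * 100, with the
    purification-loss factor applied; pct_cyto is its complement. Raw
    values outside [0, 100] (possible for K_pl != 1) are clamped and
    flagged rather than silently truncated.
    """
    a_mito = sheet.amount("p_mito")
    a_cyto = sheet.amount("cyto")
    if a_mito == 0 and a_cyto == 0:
        raise NoSignalError("no_signal: both cyto and p_mito amounts are zero")
    raw = a_mito / (a_mito + a_cyto) * sheet.K_pl * 100.0
    pct, clamped = _clamp_pct(raw)
    return FractionResult(
        pct_p_mito=pct,
        pct_cyto=100.0 - pct,
        clamped=clamped,
    )


def pct_leaflet(sheet: FractionSheet, pk_tolerance: float = 0.05) -> FractionResult:
    """Inner- vs outer-leaflet split of the OMM pool from the +/- PK lanes.

    The PK-digestible share is A_mito / (A_mito + A_mito_PK) * K_dm * 100
    (outer leaflet, exposed to the cytosol); the PK-protected complement is
    the inner leaflet. A PK lane exceeding the untreated lane beyond
    ``pk_tolerance`` (relative) is physically inconsistent and only warned
    about, since small excesses arise from blot noise.
    """
    a_mito = sheet.amount("p_mito")
    a_pk = sheet.amount("p_mito_PK")
    if a_mito == 0 and a_pk == 0:
        raise NoSignalError("no_signal: both +/-PK amounts are zero")
    warnings: list[str] = []
    if a_pk > a_mito * (1.0 + pk_tolerance):
        warnings.append("pk_inconsistent")
    raw_outer = a_mito / (a_mito + a_pk) * sheet.K_dm * 100.0
    outer, clamped = _clamp_pct(raw_outer)
    return FractionResult(
        pct_outer_leaflet=outer,
        pct_inner_leaflet=100.0 - outer,
        clamped=clamped,
        warnings=warnings,
    )


def k_pl_from_cytc(
    I_crude: float, I_pure: float, D_crude: float = 1.0, D_pure: float = 1.0
) -> float:
    """Purification-loss factor from cytochrome-C crude->pure lanes.

    Computed as the D-scaled pure/crude intensity ratio; the exact
    arithmetic behind the published factor is not specified, so the
    convention used here is documented and configurable upstream.
    """
    crude = I_crude * D_crude
    pure = I_pure * D_pure
    if crude <= 0:
        raise ValueError("crude cytochrome-C amount must be > 0")
    return pure / crude


def k_dm_from_vdac(I_no_pk: float, I_pk: float) -> float:
    """Damaged-mitochondria factor from VDAC1 +/- PK lanes.

    VDAC1 is fully membrane-embedded and PK-resistant in intact
    mitochondria, so any loss under PK reflects broken OMMs; the -PK/+PK
    ratio scales the protein-of-interest percentages accordingly.
    """
    if I_pk <= 0:
        raise ValueError("VDAC1 +PK amount must be > 0")
    return I_no_pk / I_pk
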