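"""Grape-must composition and closed-form must chemistry.

A must is characterised by its sugar content (hexoses, g/L), yeast-assimilable
nitrogen (mg N/L), malic acid (g/L), pH and sulfite status (total and free
SO2, mg/L).  Two quantities are derived from these:

* the theoretical maximum CO2 a must can release, ``0.482 * [sugar]`` —
  the stoichiometric yield of alcoholic fermentation used to anchor all
  kinetic thresholds;
* the molecular ("active") SO2 fraction of free SO2, the antimicrobial
  species, obtained from a single effective Henderson–Hasselbalch
  dissociation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MustComposition",
    "theoretical_co2_max",
    "molecular_so2",
    "fit_pka_eff",
    "read_must_table",
    "REFERENCE_MUSTS",
    "CO2_YIELD",
    "DEFAULT_PKA_EFF",
]

#: Stoichiometric CO2 yield per gram of hexose (g CO2 per g sugar).
CO2_YIELD = 0.482

#: Effective pKa of the SO2/bisulfite equilibrium at winemaking temperature
#: and trace ethanol, calibrated by least squares against five reference
#: musts with laboratory-determined active SO2 (see :func:`fit_pka_eff`).
DEFAULT_PKA_EFF = 1.86


@dataclass(frozen=True)
class MustComposition:
    """Enological composition of one grape must.

    Parameters
    ----------
    code : str
        Short label, e.g. ``"M14"`` for Merlot 2014.
    sugar : float
        Hexose content in g/L.
    assimilable_nitrogen : float
        Yeast-assimilable nitrogen in mg N/L.
    malic_acid : float
        Malic acid in g/L.
    ph : float
        Must pH.
    total_so2, free_so2 : float
        Total and free sulfite in mg/L.
    active_so2 : float or None
        Molecular SO2 in mg/L; computed from ``free_so2`` and ``ph`` when
        not provided.
    """

    code: str
    sugar: float
    assimilable_nitrogen: float
    malic_acid: float
    ph: float
    total_so2: float
    free_so2: float
    active_so2: float | None = None

    def __post_init__(self) -> None:
        if self.sugar < 0:
            raise ValueError(f"must {self.code!r}: sugar must be >= 0, got {self.sugar}")
        if not 0 < self.ph < 14:
            raise ValueError(f"must {self.code!r}: pH out of range: {self.ph}")
        if not 0 <= self.free_so2 <= self.total_so2:
            raise ValueError(
                f"must {self.code!r}: need 0 <= free SO2 <= total SO2, "
                f"got free={self.free_so2}, total={self.total_so2}"
            )
        if self.active_so2 is None:
            object.__setattr__(
                self, "active_so2", round(molecular_so2(self.free_so2, self.ph), 2)
            )

    @property
    def tco2max(self) -> float:
        """Theoretical maximum CO2 release (g/L)."""
        return theoretical_co2_max(self.sugar)


def theoretical_co2_max(sugar: float) -> float:
    """Theoretical maximum CO2 release (g/L) of a must from its sugar content.

    Parameters
    ----------
    sugar : float
        Hexose concentration in g/L.

    Returns
    -------
    float
        ``0.482 * sugar``, the CO2 stoichiometrically releasable by complete
        fermentation of the hexoses.
    """
    if not np.isfinite(sugar):
        raise ValueError(f"sugar must be finite, got {sugar}")
    if sugar < 0:
        raise ValueError(f"sugar must be >= 0, got {sugar}")
    return CO2_YIELD * sugar


def molecular_so2(free_so2: float, ph: float, pka_eff: float = DEFAULT_PKA_EFF) -> float:
    """Molecular (active) SO2 concentration from free SO2 and pH.

    Models the SO2(aq)/bisulfite equilibrium as a single dissociation with
    one effective constant, so the molecular fraction is
    ``1 / (1 + 10**(pH - pKa_eff))``.  The default ``pka_eff`` folds the
    temperature (24 degC) and trace-ethanol corrections of standard
    enological calculators into one constant.

    Parameters
    ----------
    free_so2 : float
        Free SO2 in mg/L.
    ph : float
        Must pH.
    pka_eff : float
        Effective dissociation constant, default :data:`DEFAULT_PKA_EFF`.

    Returns
    -------
    float
        Molecular SO2 in mg/L (unrounded; reference tables round to 2
        decimals).
    """
    if not np.isfinite(free_so2) or not np.isfinite(ph):
        raise ValueError("free_so2 and ph must be finite")
    if free_so2 < 0:
        raise ValueError(f"free_so2 must be >= 0, got {free_so2}")
    return free_so2 / (1.0 + 10.0 ** (ph - pka_eff))


def fit_pka_eff(
    ph: "np.ndarray | list[float]",
    free_so2: "np.ndarray | list[float]",
    active_so2: "np.ndarray | list[float]",
) -> float:
    """Calibrate the effective pKa against measured active-SO2 values.

    Least-squares fit of the single-dissociation model to
    ``(pH, free SO2, active SO2)`` triplets; used to freeze
    :data:`DEFAULT_PKA_EFF` from the five reference musts.
    """
    from scipy.optimize import minimize_scalar

    ph = np.asarray(ph, dtype=float)
    free = np.asarray(free_so2, dtype=float)
    active = np.asarray(active_so2, dtype=float)
    if not (ph.shape == free.shape == active.shape) or ph.size == 0:
        raise ValueError("ph, free_so2 and active_so2 must be equal-length, non-empty")

    def sse(pka: float) -> float:
        return float(np.sum((free / (1.0 + 10.0 ** (ph - pka)) - active) ** 2))

    res = minimize_scalar(sse, bounds=(0.5, 3.5), method="bounded")
    return float(res.x)


#: Compositions of the five reference musts (three red: M14, M15, CS15;
#: two white: SB14, SB15) used as the package's default simulated media.
REFERENCE_MUSTS: tuple[MustComposition, ...] = (
    MustComposition("SB14", 194, 157, 5.6, 3.19, 34, 7, 0.32),
    MustComposition("SB15", 203, 158, 2.9, 3.25, 67, 23, 0.91),
    MustComposition("M14", 207, 111, 2.1, 3.58, 37, 29, 0.54),
    MustComposition("M15", 219, 99, 1.9, 3.53, 46, 33, 0.68),
    MustComposition("CS15", 220, 132, 2.4, 3.57, 35, 25, 0.47),
)

_MUST_COLUMNS = {
    "code": "code",
    "sugar_g_L": "sugar",
    "nitrogen_mgN_L": "assimilable_nitrogen",
    "malic_g_L": "malic_acid",
    "pH": "ph",
    "total_SO2_mg_L": "total_so2",
    "free_SO2_mg_L": "free_so2",
}


def read_must_table(path: str | Path, sep: str | None = None) -> list[MustComposition]:
    """Read a must-composition table (CSV/TSV) into :class:`MustComposition`.

    Expected headers: ``code, sugar_g_L, nitrogen_mgN_L, malic_g_L, pH,
    total_SO2_mg_L, free_SO2_mg_L`` (optional ``active_SO2_mg_L``).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(_MUST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"must table {path} lacks columns: {sorted(missing)}")
    musts = []
    for _, row in df.iterrows():
        kwargs = {attr: row[col] for col, attr in _MUST_COLUMNS.items()}
        kwargs["code"] = str(kwargs["code"])
        if "active_SO2_mg_L" in df.columns and pd.notna(row["active_SO2_mg_L"]):
            kwargs["active_so2"] = float(row["active_SO2_mg_L"])
        musts.append(MustComposition(**kwargs))
    return musts


def write_must_table(musts: "list[MustComposition]", path: str | Path) -> None:
    """Write musts back to the CSV schema :func:`read_must_table` reads."""
    rows = [
        {
            "code": m.code,
            "sugar_g_L": m.sugar,
            "nitrogen_mgN_L": m.assimilable_nitrogen,
            "malic_g_L": m.malic_acid,
            "pH": m.ph,
            "total_SO2_mg_L": m.total_so2,
            "free_SO2_mg_L": m.free_so2,
            "active_SO2_mg_L": m.active_so2,
        }
        for m in musts
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
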