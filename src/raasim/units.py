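"""Unit conversions used throughout the package.

All internal concentrations are molar (umol/L); clinical assay results for
peptide hormones are usually mass-based (pg/ml), so conversions go through
the molecular weight.
"""

from __future__ import annotations

from .errors import DomainError

__all__ = [
    "pg_per_ml_to_umol_per_L",
    "umol_per_L_to_pg_per_ml",
    "mg_to_umol",
    "umol_to_mg",
]


def pg_per_ml_to_umol_per_L(value_pg_per_ml: float, mw_kda: float) -> float:
    """Convert a mass concentration (pg/ml) to a molar one (umol/L).

    1 pg/ml = 1 ng/L = 1e-3 ug/L; dividing by the molecular weight in
    kDa (= ug/umol * 1e-3... i.e. 1 kDa = 1000 g/mol = 1000 ug/umol) gives

        umol/L = (pg/ml) / (MW_kDa * 1000) * 1e-3 * 1000
               = (pg/ml) / MW_kDa * 1e-6 * ...

    worked out once: 69 pg/ml of a 57-kDa protein is
    69e-12 g/ml = 69e-9 g/L; / 57000 g/mol = 1.21e-12 mol/L = 1.21e-6 umol/L.
    """
    if value_pg_per_ml < 0 or mw_kda <= 0:
        raise DomainError("concentration must be >= 0 and molecular weight > 0")
    grams_per_L = value_pg_per_ml * 1e-12 * 1000.0
    mol_per_L = grams_per_L / (mw_kda * 1000.0)
    return mol_per_L * 1e6


def umol_per_L_to_pg_per_ml(value_umol_per_L: float, mw_kda: float) -> float:
    """Inverse of :func:`pg_per_ml_to_umol_per_L`."""
    if value_umol_per_L < 0 or mw_kda <= 0:
        raise DomainError("concentration must be >= 0 and molecular weight > 0")
    mol_per_L = value_umol_per_L * 1e-6
    grams_per_L = mol_per_L * mw_kda * 1000.0
    return grams_per_L / 1000.0 * 1e12


def mg_to_umol(mass_mg: float, mw_g_per_mol: float) -> float:
    """Convert a dose in mg to umol via the molecular weight in g/mol."""
    if mass_mg < 0 or mw_g_per_mol <= 0:
        raise DomainError("mass must be >= 0 and molecular weight > 0")
    return mass_mg / mw_g_per_mol * 1000.0


def umol_to_mg(amount_umol: float, mw_g_per_mol: float) -> float:
    """Inverse of :func:`mg_to_umol`."""
    if amount_umol < 0 or mw_g_per_mol <= 0:
        raise DomainError("amount must be >= 0 and molecular weight > 0")
    return amount_umol * mw_g_per_mol / 1000.0
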