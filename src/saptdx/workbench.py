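"""Model-system fixtures, scan drivers and comparison statistics.

Fixtures (coordinates in bohr):

- ``h2_h2_T``: T-shaped H2...H2; probe monomer A along x at the origin with
  variable bond R_HH, spectator monomer B along the intermolecular (z) axis
  with its bond fixed at 1.44 a0 and its center 6.21 a0 from A's center.
- ``he_h2_T``: T-shaped He...H2; the H2 bond (monomer B) lies along x with
  midpoint at the origin, He on the z axis at distance R from the midpoint.
  Ground state uses r(HH) = 1.44 a0; the 1Sigma_u+ excited state 2.44 a0.
- ``be_be``: collinear Be2 at 4.6 a0 (equilibrium) or a supplied distance.

The exact reflection x -> -x of these fixtures classifies gerade/ungerade
monomer states and drives excited-root selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from . import __version__
from .exchange import FirstOrderDecomposition, frozen_core_correction
from .geminal import exchange_S4_geminal
from .geometry import DimerGeometry, make_dimer
from .integrals.engine import DimerSystem, build_dimer_system
from .states import MethodSpec, MonomerState, solve_monomer
from .tensors import transform_interaction_tensors

HARTREE_TO_MICROHARTREE = 1e6


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_fixture(name: str, **params) -> DimerGeometry:
    """Geometries of the model systems; see the module docstring."""
    if name == "h2_h2_T":
        r_probe = params.get("r_hh", 1.44)
        r_spec = params.get("r_spectator", 1.44)
        R = params.get("r_centers", 6.21)
        return make_dimer(
            ["H", "H", "H", "H"],
            [[-r_probe / 2, 0, 0], [r_probe / 2, 0, 0],
             [0, 0, R - r_spec / 2], [0, 0, R + r_spec / 2]],
            "AABB",
        )
    if name in ("he_h2_T", "he_h2_T_ground", "he_h2_T_excited"):
        r_hh = params.get("r_hh", 2.44 if name.endswith("excited") else 1.44)
        R = params.get("r", 6.40 if name.endswith("ground") else 4.43)
        return make_dimer(
            ["He", "H", "H"],
            [[0, 0, R], [-r_hh / 2, 0, 0], [r_hh / 2, 0, 0]],
            "ABB",
        )
    if name == "be_be":
        R = params.get("r", 4.6)
        return make_dimer(["Be", "Be"], [[0, 0, 0], [0, 0, R]], "AB")
    raise ValueError(
        f"unknown fixture {name!r}; available: h2_h2_T, he_h2_T, "
        "he_h2_T_ground, he_h2_T_excited, be_be"
    )


# ---------------------------------------------------------------------------
# single points
# ---------------------------------------------------------------------------


def first_order_decomposition(system: DimerSystem, msA: MonomerState,
                              msB: MonomerState) -> FirstOrderDecomposition:
    """S^2/S^4 decomposition for two solved monomer states (geminal path)."""
    t = transform_interaction_tensors(
        system, msA.geminal.orbitals, msB.geminal.orbitals
    )
    return exchange_S4_geminal(msA.geminal, msB.geminal, t)


def compute_point(geometry: DimerGeometry, basis, specA: MethodSpec,
                  specB: MethodSpec):
    """Build the dimer, solve both monomers, return the decomposition."""
    system = build_dimer_system(geometry, basis)
    msA = solve_monomer(system, "A", specA)
    msB = solve_monomer(system, "B", specB)
    return first_order_decomposition(system, msA, msB), msA, msB, system


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------


@dataclass
class ScanSpec:
    fixture: str
    coordinate: str                 # fixture parameter being scanned
    grid: list[float]
    basis: str = "aug-cc-pvtz"
    method_a: MethodSpec = field(default_factory=MethodSpec)
    method_b: MethodSpec = field(default_factory=MethodSpec)
    fixture_params: dict = field(default_factory=dict)

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if len(g) >= 2 and not np.all(np.diff(g) > 0):
            raise ValueError("scan grid must be strictly increasing")

    def provenance(self) -> dict:
        return {
            "code_version": __version__,
            "fixture": self.fixture,
            "coordinate": self.coordinate,
            "grid": list(map(float, self.grid)),
            "basis": str(self.basis),
            "method_a": vars(self.method_a).copy(),
            "method_b": vars(self.method_b).copy(),
            "fixture_params": dict(self.fixture_params),
            "units": "bohr / hartree",
        }


def run_scan(spec: ScanSpec, progress=None) -> pd.DataFrame:
    """Per-point first-order decomposition along the scan grid.

    Failures at individual points are recorded (NaN row) rather than fatal;
    an all-failed scan raises.
    """
    rows = []
    n_fail = 0
    for x in spec.grid:
        params = dict(spec.fixture_params)
        params[spec.coordinate] = x
        try:
            geo = make_fixture(spec.fixture, **params)
            dec, msA, msB, _ = compute_point(geo, spec.basis, spec.method_a,
                                             spec.method_b)
            row = {spec.coordinate: x, **dec.as_dict(),
                   "E_A": msA.energy, "E_B": msB.energy}
        except Exception as exc:  # pragma: no cover - defensive
            n_fail += 1
            row = {spec.coordinate: x, "error": str(exc)}
        rows.append(row)
        if progress:
            progress(row)
    if n_fail == len(spec.grid):
        raise RuntimeError("every scan point failed")
    df = pd.DataFrame(rows)
    for col in ("E_exch_S2", "E_exch_propS4", "E_exch_S4"):
        if col in df:
            df[col + "_uEh"] = df[col] * HARTREE_TO_MICROHARTREE
    df.attrs["provenance"] = spec.provenance()
    return df


def save_table(df: pd.DataFrame, path: str) -> None:
    if str(path).endswith(".json"):
        payload = {
            "provenance": df.attrs.get("provenance", {}),
            "rows": df.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        with open(path, "w") as fh:
            prov = df.attrs.get("provenance")
            if prov:
                fh.write("# provenance: " + json.dumps(prov) + "\n")
            df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# comparison statistics
# ---------------------------------------------------------------------------


def relative_error(approx, ref) -> np.ndarray:
    """(approx - ref)/|ref| in percent, sign retained."""
    approx = np.asarray(approx, dtype=float)
    ref = np.asarray(ref, dtype=float)
    return 100.0 * (approx - ref) / np.abs(ref)


def recovery_fraction(approx, ref) -> np.ndarray:
    """approx/ref in percent."""
    return 100.0 * np.asarray(approx, dtype=float) / np.asarray(ref, dtype=float)


def max_abs_relative_deviation(approx, ref) -> float:
    return float(np.max(np.abs(relative_error(approx, ref))))


def zero_crossing(x, y) -> float:
    """Location of the sign change of y(x) by monotone cubic interpolation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sign = np.sign(y)
    idx = np.where(sign[:-1] * sign[1:] < 0)[0]
    if len(idx) == 0:
        raise ValueError("no bracketing sign change on the grid")
    interp = PchipInterpolator(x, y)
    i = idx[0]
    return float(brentq(interp, x[i], x[i + 1], xtol=1e-10))


def analyze(table: pd.DataFrame, what: str, component: str = "E_exch_S2",
            ref_table: pd.DataFrame | None = None):
    """Comparison statistics between a table and a reference on the same grid."""
    if what == "zero_crossing":
        xcol = [c for c in table.columns if not c.startswith("E_") and
                table[c].dtype.kind == "f"][0]
        return zero_crossing(table[xcol].values, table[component].values)
    if ref_table is None:
        raise ValueError(f"analysis {what!r} requires a reference table")
    a = table[component].values
    r = ref_table[component].values
    if len(a) != len(r):
        raise ValueError("tables are not on the same grid")
    if what == "relative_error":
        return relative_error(a, r)
    if what == "recovery_fraction":
        return recovery_fraction(a, r)
    if what == "max_abs_relative_deviation":
        return max_abs_relative_deviation(a, r)
    raise ValueError(f"unknown analysis {what!r}")


__all__ = [
    "make_fixture", "compute_point", "first_order_decomposition", "ScanSpec",
    "run_scan", "save_table", "relative_error", "recovery_fraction",
    "max_abs_relative_deviation", "zero_crossing", "analyze",
    "frozen_core_correction",
]
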