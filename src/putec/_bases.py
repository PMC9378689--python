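"""Idealized planar nucleobase templates and pairing geometry.

Templates are constructed deterministically from idealized planar bond
geometry (regular hexagon / fused pentagon rings, radial exocyclic
substituents) rather than loaded from a frozen coordinate file, so the
construction itself documents the provenance and is bit-stable across
runs.  Coordinates live in the base plane (z = 0) with the glycosidic
nitrogen's ring-radial direction defining the local frame used to attach
the sugar.

These templates feed the synthetic duplex generator and in-silico base
substitution; they are idealized geometry, not refined coordinates.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize

RING6_BOND = 1.38  # aromatic C-C/C-N bond, Angstrom
C_O_BOND = 1.23  # exocyclic carbonyl
C_N_BOND = 1.34  # exocyclic amino
N_C1P_BOND = 1.47  # glycosidic bond
HBOND_TARGET = 2.90  # donor-acceptor heavy atom distance used in construction

PURINES = {"A", "G", "DA", "DG"}
PYRIMIDINES = {"C", "U", "T", "DC", "DT"}

#: ring atoms defining the base plane, per one-letter base code
RING_ATOMS = {
    "A": ["N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"],
    "G": ["N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"],
    "C": ["N1", "C2", "N3", "C4", "C5", "C6"],
    "U": ["N1", "C2", "N3", "C4", "C5", "C6"],
    "T": ["N1", "C2", "N3", "C4", "C5", "C6"],
}

GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "U": "N1", "T": "N1"}


def _hexagon(names: list[str]) -> dict[str, np.ndarray]:
    """Regular hexagon with circumradius equal to the ring bond length."""
    out = {}
    for i, nm in enumerate(names):
        ang = math.radians(90.0 + 60.0 * i)
        out[nm] = RING6_BOND * np.array([math.cos(ang), math.sin(ang), 0.0])
    return out


def _radial(coords: dict[str, np.ndarray], center: np.ndarray, atom: str) -> np.ndarray:
    v = coords[atom] - center
    return v / np.linalg.norm(v)


@lru_cache(maxsize=None)
def base_template(code: str) -> dict[str, np.ndarray]:
    """Heavy-atom coordinates of an idealized planar base, z = 0.

    ``code`` is a one-letter base code (A/C/G/U/T).  Includes the C1'
    position along the glycosidic-nitrogen radial so callers can attach
    a sugar.
    """
    code = code.upper()
    if code not in GLYCOSIDIC_N:
        raise ValueError(f"unknown base code {code!r}")
    ring6 = ["N1", "C2", "N3", "C4", "C5", "C6"]
    coords = _hexagon(ring6)
    c6ctr = np.zeros(3)

    if code in ("A", "G"):
        # fused imidazole sharing the C4-C5 edge, on the far side from N1
        c4, c5 = coords["C4"], coords["C5"]
        edge_mid = 0.5 * (c4 + c5)
        out_dir = edge_mid / np.linalg.norm(edge_mid)  # away from hexagon center
        e = np.linalg.norm(c5 - c4)
        apothem = e / (2.0 * math.tan(math.radians(36.0)))
        r5 = e / (2.0 * math.sin(math.radians(36.0)))
        p5ctr = edge_mid + out_dir * apothem
        # pentagon vertex order around center: C4, N9, C8, N7, C5
        a4 = math.atan2(c4[1] - p5ctr[1], c4[0] - p5ctr[0])
        a5 = math.atan2(c5[1] - p5ctr[1], c5[0] - p5ctr[0])
        # step direction chosen to go C4 -> N9 -> C8 -> N7 -> C5
        step = (a5 - a4) % (2 * math.pi)
        sgn = 1.0 if abs(step - math.radians(288.0)) < abs(step - math.radians(72.0)) else -1.0
        for k, nm in enumerate(["N9", "C8", "N7"], start=1):
            ang = a4 + sgn * k * math.radians(72.0)
            coords[nm] = p5ctr + r5 * np.array([math.cos(ang), math.sin(ang), 0.0])
        if code == "A":
            coords["N6"] = coords["C6"] + _radial(coords, c6ctr, "C6") * C_N_BOND
        else:
            coords["O6"] = coords["C6"] + _radial(coords, c6ctr, "C6") * C_O_BOND
            coords["N2"] = coords["C2"] + _radial(coords, c6ctr, "C2") * C_N_BOND
        coords["C1'"] = coords["N9"] + _radial(coords, p5ctr, "N9") * N_C1P_BOND
    else:
        coords["O2"] = coords["C2"] + _radial(coords, c6ctr, "C2") * C_O_BOND
        if code == "C":
            coords["N4"] = coords["C4"] + _radial(coords, c6ctr, "C4") * C_N_BOND
        else:
            coords["O4"] = coords["C4"] + _radial(coords, c6ctr, "C4") * C_O_BOND
            if code == "T":
                coords["C7"] = coords["C5"] + _radial(coords, c6ctr, "C5") * 1.50
        coords["C1'"] = coords["N1"] + _radial(coords, c6ctr, "N1") * N_C1P_BOND
    return {k: v.copy() for k, v in coords.items()}


#: Watson-Crick edge hydrogen bonds as (purine atom, pyrimidine atom)
WC_EDGE = {
    ("A", "U"): [("N1", "N3"), ("N6", "O4")],
    ("A", "T"): [("N1", "N3"), ("N6", "O4")],
    ("G", "C"): [("N1", "N3"), ("O6", "N4"), ("N2", "O2")],
}


def _ring6_center(coords: dict[str, np.ndarray]) -> np.ndarray:
    return np.mean([coords[n] for n in ["N1", "C2", "N3", "C4", "C5", "C6"]], axis=0)


def _edge_direction(coords: dict[str, np.ndarray], atom: str) -> np.ndarray:
    """Outward in-plane direction at an edge atom (radial from 6-ring center)."""
    return _radial(coords, _ring6_center(coords), atom)


def _fit2d(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares 2D rotation + translation (no reflection), z ignored."""
    s2, d2 = src[:, :2], dst[:, :2]
    sc, dc = s2.mean(axis=0), d2.mean(axis=0)
    h = (s2 - sc).T @ (d2 - dc)
    u, _, vt = np.linalg.svd(h)
    r = vt.T @ u.T
    if np.linalg.det(r) < 0:
        vt[-1] *= -1
        r = vt.T @ u.T
    t = dc - r @ sc
    r3 = np.eye(3)
    r3[:2, :2] = r
    return r3, np.array([t[0], t[1], 0.0])


@lru_cache(maxsize=None)
def wc_pair_template(pu: str, py: str) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Coordinates of an idealized Watson-Crick pair, both bases coplanar.

    The purine keeps its template frame; the pyrimidine is placed by a
    2D Procrustes fit of its WC-edge atoms (plus its ring center, to pin
    orientation) onto target points constructed at ``HBOND_TARGET`` along
    the purine edge radials.  Both mirror states of the planar template
    are tried; the one with the lower residual and the larger C1'-C1'
    separation wins, which selects the antiparallel arrangement.
    """
    bonds = WC_EDGE[(pu, py)]
    a = base_template(pu)
    b_raw = base_template(py)
    names = list(b_raw)

    # target points: hydrogen bonds roughly parallel, all along the radial
    # at the central (N1) edge atom of the purine
    d1 = _edge_direction(a, bonds[0][0])
    dirs = [d1 for _ in bonds]
    edge_targets = [a[nm_pu] + d * HBOND_TARGET for (nm_pu, _), d in zip(bonds, dirs)]
    src_names = [nm_py for _, nm_py in bonds]
    dst = np.array(edge_targets)

    best = None
    for mirror in (False, True):
        tpl = {k: (v * np.array([1.0, -1.0, 1.0]) if mirror else v) for k, v in b_raw.items()}
        src = np.array([tpl[nm] for nm in src_names])
        r3, t = _fit2d(src, dst)
        moved = {nm: r3 @ tpl[nm] + t for nm in names}
        resid = float(np.sum((np.array([moved[nm] for nm in src_names]) - dst) ** 2))
        c1c1 = float(np.linalg.norm(a["C1'"] - moved["C1'"]))
        hb_set = set(bonds)
        min_other = min(
            float(np.linalg.norm(a[x] - moved[y]))
            for x in a for y in moved if (x, y) not in hb_set
        )
        clashed = min_other < 2.5  # mirror state folding the bases onto each other
        key = (clashed, round(resid, 6), -c1c1)
        if best is None or key < best[0]:
            best = (key, moved)
    b = best[1]

    # recentre: mean donor-acceptor distance exactly HBOND_TARGET
    mean_hb = np.mean([np.linalg.norm(a[x] - b[y]) for x, y in bonds])
    shift = d1 * (mean_hb - HBOND_TARGET)
    b = {k: v - shift for k, v in b.items()}

    # swing each C1' about its glycosidic nitrogen (in plane, bond length
    # kept) to the canonical WC C1'-C1' separation of 10.4 A
    a = {k: v.copy() for k, v in a.items()}
    n_a, n_b = a[GLYCOSIDIC_N[pu]], b[GLYCOSIDIC_N[py]]
    v_a, v_b = a["C1'"] - n_a, b["C1'"] - n_b

    def _rot_z(v, th):
        c, s = math.cos(th), math.sin(th)
        return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], v[2]])

    def c1_cost(thetas):
        p = n_a + _rot_z(v_a, thetas[0])
        q = n_b + _rot_z(v_b, thetas[1])
        return (np.linalg.norm(p - q) - 10.4) ** 2 + 1e-4 * (thetas[0] - thetas[1]) ** 2

    sol = minimize(c1_cost, x0=[0.0, 0.0], method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 4000})
    a["C1'"] = n_a + _rot_z(v_a, sol.x[0])
    b["C1'"] = n_b + _rot_z(v_b, sol.x[1])
    return (a, {k: v.copy() for k, v in b.items()})


def pair_geometry_report(pu: str, py: str) -> dict:
    """Diagnostics for a pair template: hbond distances and C1'-C1'."""
    a, b = wc_pair_template(pu, py)
    hb = {f"{x}-{y}": float(np.linalg.norm(a[x] - b[y])) for x, y in WC_EDGE[(pu, py)]}
    return {"hbonds": hb, "c1c1": float(np.linalg.norm(a["C1'"] - b["C1'"]))}
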