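#!/usr/bin/env python
"""Regenerate the frozen Kelvin-cell closed forms (spinecage/_kelvin_forms.py).

Derivation: the stretched-Kelvin strut lattice (12 nodes, 24 Euler-Bernoulli
beams per periodic cell, rigid joints) is homogenized symbolically.  For each
unit macroscopic strain the periodic corrections are reduced to their exact
symmetry orbits (extracted numerically as +-1 patterns from the frame
solution — the orbits are parameter-independent), the quadratic energy is
minimized via the adjugate formula, and 2*U_min/V gives the stiffness
entries C11, C33, C12, C13, C44, C66 as explicit algebraic functions of
(R, E0, G0, A, I, J).  The result is verified against the numeric beam frame
over a grid of (R, r/L) to 1e-8 before the module is written.

Requires sympy; runtime a few minutes.  Run from the repository root:

    python scripts/derive_kelvin_forms.py
"""

import sys
import time
from pathlib import Path

import numpy as np
import sympy as sp

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from spinecage.beamframe import (  # noqa: E402
    _beam_stiffness,
    _local_frame,
    homogenize_kelvin_frame,
    kelvin_network,
)

NODES, EDGES = kelvin_network()


def solve_numeric(Rv, t, Em, E0=1.0, nu0=0.3):
    """Periodic frame solve returning the gauge-fixed correction vector."""
    stretch = np.array([1.0, 1.0, Rv])
    X = NODES * stretch
    G0 = E0 / (2 * (1 + nu0))
    L_obl = 0.25 * np.sqrt(1 + Rv * Rv)
    r = t * L_obl
    A, Iy, J = np.pi * r * r, np.pi * r**4 / 4, np.pi * r**4 / 2
    K = np.zeros((72, 72))
    elems = []
    for i, j, shift in EDGES:
        P1 = X[i]
        P2 = (NODES[j] + shift) * stretch
        d = P2 - P1
        L = np.linalg.norm(d)
        Rf = _local_frame(d)
        k_loc = _beam_stiffness(E0, G0, A, Iy, J, L)
        T = np.zeros((12, 12))
        for blk in range(4):
            T[3 * blk : 3 * blk + 3, 3 * blk : 3 * blk + 3] = Rf
        kg = T.T @ k_loc @ T
        dofs = np.r_[6 * i + np.arange(6), 6 * j + np.arange(6)]
        K[np.ix_(dofs, dofs)] += kg
        elems.append((P1, P2, kg, dofs))
    f = np.zeros(72)
    for P1, P2, kg, dofs in elems:
        q = np.zeros(12)
        q[0:3] = Em @ P1
        q[6:9] = Em @ P2
        f[dofs] -= kg @ q
    free = np.arange(3, 72)
    w = np.zeros(72)
    w[free] = np.linalg.solve(K[np.ix_(free, free)], f[free])
    wr = w.reshape(12, 6)
    wr[:, :3] -= wr[:, :3].mean(axis=0)
    return wr.reshape(-1)


def extract_pattern(Em):
    """Exact +-1 symmetry orbits of the periodic correction for a strain."""
    wa = solve_numeric(1.73, 0.11, Em)
    wb = solve_numeric(2.61, 0.23, Em)
    sa, sb = np.abs(wa).max(), np.abs(wb).max()
    nz = (np.abs(wa) > 1e-9 * sa) | (np.abs(wb) > 1e-9 * sb)
    groups = []
    for d in np.where(nz)[0]:
        for g in groups:
            d0 = g[0][0]
            ra, rb = wa[d] / wa[d0], wb[d] / wb[d0]
            if abs(ra - rb) < 1e-7 and abs(abs(ra) - 1) < 1e-7:
                g.append((d, int(np.sign(ra))))
                break
        else:
            groups.append([(d, 1)])
    return groups


R = sp.symbols("R", positive=True)
E0s, G0s, As, Is, Js = sp.symbols("E0 G0 A I J", positive=True)
Lb, Lo = sp.symbols("Lb Lo", positive=True)
SUBS_FINAL = {Lo: sp.sqrt(1 + R**2) / 4, Lb: sp.sqrt(2) / 4}


def pos_s(i, shift=(0, 0, 0)):
    sc = [1, 1, R]
    return sp.Matrix(
        [(sp.nsimplify(NODES[i][a]) + shift[a]) * sc[a] for a in range(3)]
    )


def beam_energy(P1, P2, u1, phi1, u2, phi2):
    """Symbolic Euler-beam energy; strut lengths stay opaque symbols so the
    algebra remains rational until the final substitution."""
    d = P2 - P1
    horizontal = sp.simplify(d[2]) == 0
    L = Lb if horizontal else Lo
    x = d / L
    ref = sp.Matrix([0, 0, 1])
    cr = ref.cross(x)
    n2 = sp.simplify(cr.dot(cr) * L**2)  # rational
    y = cr * L / sp.sqrt(n2)
    z = x.cross(y)
    U = E0s * As / (2 * L) * x.dot(u2 - u1) ** 2
    U += G0s * Js / (2 * L) * x.dot(phi2 - phi1) ** 2
    for tdir, bdir, sgn in ((y, z, 1), (z, y, -1)):
        v1, v2 = tdir.dot(u1), tdir.dot(u2)
        p1, p2 = sgn * bdir.dot(phi1), sgn * bdir.dot(phi2)
        U += E0s * Is / (2 * L**3) * (
            12 * (v2 - v1) ** 2
            - 12 * L * (v2 - v1) * (p1 + p2)
            + 4 * L**2 * (p1**2 + p1 * p2 + p2**2)
        )
    return U


def solve_case(name, Em_num, Em_sym):
    t0 = time.time()
    groups = extract_pattern(Em_num)
    syms = [sp.Symbol(f"g{k}") for k in range(len(groups))]
    wvec = [sp.Integer(0)] * 72
    for s, members in zip(syms, groups):
        for d, sign in members:
            wvec[d] = sign * s
    w = {k: sp.Matrix(wvec[6 * k : 6 * k + 3]) for k in range(12)}
    th = {k: sp.Matrix(wvec[6 * k + 3 : 6 * k + 6]) for k in range(12)}
    U = sp.Integer(0)
    for i, j, shift in EDGES:
        P1 = pos_s(i)
        P2 = pos_s(j, shift)
        U += beam_energy(P1, P2, Em_sym * P1 + w[i], th[i], Em_sym * P2 + w[j], th[j])
    U = sp.expand(U)
    if syms:
        H = sp.Matrix([[sp.expand(sp.diff(U, a, b)) for b in syms] for a in syms])
        c = sp.Matrix(
            [sp.expand(sp.diff(U, a).subs({s_: 0 for s_ in syms})) for a in syms]
        )
        U0 = U.subs({s_: 0 for s_ in syms})
        det = sp.expand(H.det(method="berkowitz"))
        adj = H.adjugate()
        quad = sp.expand((c.T * adj * c)[0, 0])
        U = U0 - quad / (2 * det)
    val = (2 * U / R).subs(SUBS_FINAL)
    print(f"  {name}: {len(groups)} orbit scalars, {time.time()-t0:.1f}s", flush=True)
    return val


def main() -> None:
    half = sp.Rational(1, 2)
    cases = {
        "C11": (np.diag([1.0, 0, 0]), sp.diag(1, 0, 0)),
        "C33": (np.diag([0.0, 0, 1]), sp.diag(0, 0, 1)),
        "Qxxyy": (np.diag([1.0, 1, 0]), sp.diag(1, 1, 0)),
        "Qxxzz": (np.diag([1.0, 0, 1]), sp.diag(1, 0, 1)),
        "C44": (
            np.array([[0, 0, 0.5], [0, 0, 0], [0.5, 0, 0]]),
            sp.Matrix([[0, 0, half], [0, 0, 0], [half, 0, 0]]),
        ),
        "C66": (
            np.array([[0, 0.5, 0], [0.5, 0, 0], [0, 0, 0]]),
            sp.Matrix([[0, half, 0], [half, 0, 0], [0, 0, 0]]),
        ),
    }
    print("deriving closed forms...", flush=True)
    out = {}
    for name, (Em_num, Em_sym) in cases.items():
        out[name] = solve_case(name, Em_num, Em_sym)
    out["C12"] = (out.pop("Qxxyy") - 2 * out["C11"]) / 2
    out["C13"] = (out.pop("Qxxzz") - out["C11"] - out["C33"]) / 2

    print("simplifying...", flush=True)
    simplified = {}
    for k, e in out.items():
        s = sp.cancel(sp.together(e))
        try:
            s2 = sp.simplify(s)
            s = s2 if sp.count_ops(s2) < sp.count_ops(s) else s
        except Exception:
            pass
        simplified[k] = s

    print("verifying against the numeric frame...", flush=True)
    syms_all = (R, E0s, G0s, As, Is, Js)
    order = ["C11", "C33", "C12", "C13", "C44", "C66"]
    fns = {k: sp.lambdify(syms_all, simplified[k], "numpy") for k in order}
    for Rv in (1.0, 1.4, 2.2, 3.0):
        for t in (0.06, 0.15, 0.3):
            C = homogenize_kelvin_frame(Rv, t).C_eff
            Lo_v = 0.25 * np.sqrt(1 + Rv * Rv)
            r = t * Lo_v
            Av, Iv, Jv = np.pi * r * r, np.pi * r**4 / 4, np.pi * r**4 / 2
            ref = {"C11": C[0, 0], "C33": C[2, 2], "C12": C[0, 1],
                   "C13": C[0, 2], "C44": C[3, 3], "C66": C[5, 5]}
            for k in order:
                got = fns[k](Rv, 1.0, 1 / 2.6, Av, Iv, Jv)
                rel = abs(got - ref[k]) / max(abs(ref[k]), 1e-14)
                assert rel < 1e-8, (Rv, t, k, rel)
    print("verification passed", flush=True)

    from sympy.printing.pycode import pycode

    repl, reduced = sp.cse([simplified[k] for k in order], optimizations="basic")
    lines = [
        '"""Frozen closed-form stiffness entries of the stretched Kelvin lattice.',
        "",
        "Derived symbolically by energy minimization of the periodic 24-strut",
        "tetrakaidecahedron frame (Euler-Bernoulli beams, rigid joints), with the",
        "periodic corrections reduced to their exact symmetry orbits.  The cell has",
        "unit in-plane period, height R, strut inclination tan(theta) = R; section",
        "properties A, I, J refer to the circular strut cross-section, E0/G0 to the",
        "solid.  Entries are Voigt: C11 (transverse), C33 (rise), C12, C13, C44",
        "(out-of-plane shear), C66 (in-plane shear), in units of stress of E0.",
        '"""',
        "",
        "from math import sqrt",
        "",
        "",
        "def tetragonal_stiffness_entries(R, E0, G0, A, I, J):",
        '    """Return (C11, C33, C12, C13, C44, C66) for aspect ratio R >= 1."""',
    ]
    for sym, expr in repl:
        lines.append(f"    {sym} = {pycode(expr)}")
    for k, e in zip(order, reduced):
        lines.append(f"    c{k} = {pycode(e)}")
    names = ", ".join(f"c{k}" for k in order)
    lines.append(f"    return ({names})")
    code = "\n".join(lines).replace("math.sqrt", "sqrt") + "\n"
    target = Path(__file__).resolve().parents[1] / "src/spinecage/_kelvin_forms.py"
    target.write_text(code)
    print(f"wrote {target}")


if __name__ == "__main__":
    main()
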