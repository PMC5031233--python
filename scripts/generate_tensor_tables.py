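"""Regenerate krigfield/_tensor_tables.py.

Derives, with sympy, the real regular solid harmonics S_lm (Racah
normalization, l <= 4) as Cartesian polynomials, and the rank-pair
electrostatic interaction tensors

    T[l1,l2](R)  such that  E = sum Q^A_{l1 m1} T_{m1 m2}(R) Q^B_{l2 m2}

for l1 + l2 <= 4 (quadrupole-quadrupole truncation level L = l1+l2+1 = 5).
The tensors are obtained by applying S_{l1 m1}(grad_A) S_{l2 m2}(grad_B) to
the Coulomb kernel 1/|r_A - r_B| and normalizing by the Fischer norms
(2l-1)!!.  Output is plain vectorized numpy code; run this script only when
changing conventions, then re-run the electrostatics test suite (the
point-charge oracle validates every generated entry).

Usage: python scripts/generate_tensor_tables.py > src/krigfield/_tensor_tables.py
"""
import sys

import sympy as sp

x, y, z = sp.symbols("x y z", real=True)
X, Y, Z = sp.symbols("X Y Z", real=True)


def complex_solid(l, m):
    am = abs(m)
    s = sp.Integer(0)
    for k in range(0, (l - am) // 2 + 1):
        term = (
            (sp.Rational(-1, 2) * (x + sp.I * y)) ** (am + k)
            * ((x - sp.I * y) / 2) ** k
            * z ** (l - am - 2 * k)
        )
        s += term / (sp.factorial(am + k) * sp.factorial(k) * sp.factorial(l - am - 2 * k))
    s = sp.sqrt(sp.factorial(l + am) * sp.factorial(l - am)) * s
    if m < 0:
        s = (-1) ** am * sp.conjugate(s)
        s = s.rewrite(sp.conjugate).subs(
            {sp.conjugate(x): x, sp.conjugate(y): y, sp.conjugate(z): z}
        )
    return sp.expand(s)


def real_solid(l, m, kind):
    if m == 0:
        return complex_solid(l, 0)
    Rp, Rm = complex_solid(l, m), complex_solid(l, -m)
    if kind == "c":
        e = ((-1) ** m * Rp + Rm) / sp.sqrt(2)
    else:
        e = ((-1) ** m * Rp - Rm) / (sp.I * sp.sqrt(2))
    return sp.expand(sp.simplify(e))


COMPONENTS = []
for l in range(5):
    COMPONENTS.append((l, 0, "0"))
    for m in range(1, l + 1):
        COMPONENTS.append((l, m, "c"))
        COMPONENTS.append((l, m, "s"))

POLYS = {c: real_solid(c[0], c[1], "0" if c[1] == 0 else c[2]) for c in COMPONENTS}
FISCHER = {0: 1, 1: 1, 2: 3, 3: 15, 4: 105}


def apply_diff(op_poly, f):
    pd = sp.Poly(op_poly, x, y, z)
    out = sp.Integer(0)
    for mono, coef in zip(pd.monoms(), pd.coeffs()):
        out += coef * sp.diff(f, x, mono[0], y, mono[1], z, mono[2])
    return out


def poly_to_code(expr, vars_, powmax):
    """Render a polynomial as a numpy expression string with float coefficients."""
    p = sp.Poly(sp.expand(expr), *vars_)
    terms = []
    for mono, coef in zip(p.monoms(), p.coeffs()):
        c = float(coef)
        factors = [repr(c)]
        for v, e in zip(vars_, mono):
            if e == 1:
                factors.append(str(v))
            elif e > 1:
                factors.append(f"{v}**{e}")
        terms.append("*".join(factors))
    return " + ".join(terms) if terms else "0.0*X"


def main(out=sys.stdout):
    w = out.write
    w('"""Generated by scripts/generate_tensor_tables.py -- do not edit by hand.\n\n')
    w("Real regular solid harmonics (Racah normalization, canonical component\n")
    w("order Q00, Q10, Q11c, Q11s, ..., Q44s) and rank-pair electrostatic\n")
    w('interaction tensors for the quadrupole-quadrupole (L=5) truncation.\n"""\n')
    w("import numpy as np\n\n")
    w("COMPONENT_NAMES = [\n")
    names = []
    for (l, m, k) in COMPONENTS:
        names.append(f"Q{l}{m}" + ("" if k == "0" else k))
    w("    " + ", ".join(repr(n) for n in names) + ",\n]\n\n")
    w("RANK_SLICES = {0: slice(0, 1), 1: slice(1, 4), 2: slice(4, 9), "
      "3: slice(9, 16), 4: slice(16, 25)}\n\n")

    # solid harmonics evaluator
    w("def solid_harmonics(xyz):\n")
    w('    """Evaluate the 25 real solid harmonics at Cartesian points.\n\n')
    w("    xyz: array (..., 3).  Returns array (..., 25) in canonical order.\n")
    w('    """\n')
    w("    xyz = np.asarray(xyz, dtype=float)\n")
    w("    x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]\n")
    w("    out = np.empty(xyz.shape[:-1] + (25,), dtype=float)\n")
    for i, c in enumerate(COMPONENTS):
        code = poly_to_code(POLYS[c], (x, y, z), 4)
        code = code.replace(repr(1.0) + "*", "")
        w(f"    out[..., {i}] = {code}\n")
    w("    return out\n\n\n")

    # interaction tensor blocks
    w("def _r_powers(X, Y, Z):\n")
    w("    r2 = X * X + Y * Y + Z * Z\n")
    w("    r = np.sqrt(r2)\n")
    w("    return r2, r\n\n\n")
    block_names = {}
    for l1 in range(5):
        for l2 in range(5 - l1):
            L = l1 + l2
            rows = [c for c in COMPONENTS if c[0] == l1]
            cols = [c for c in COMPONENTS if c[0] == l2]
            fname = f"_t_{l1}{l2}"
            block_names[(l1, l2)] = fname
            w(f"def {fname}(X, Y, Z):\n")
            w("    r2, r = _r_powers(X, Y, Z)\n")
            w(f"    inv = 1.0 / (r2**{L} * r)\n")
            w(f"    T = np.empty(np.shape(X) + ({2*l1+1}, {2*l2+1}), dtype=float)\n")
            for i, c1 in enumerate(rows):
                g1 = sp.cancel(sp.together(apply_diff(POLYS[c1], 1 / sp.sqrt(x**2 + y**2 + z**2))))
                for j, c2 in enumerate(cols):
                    g = apply_diff(POLYS[c2], g1)
                    g = g.subs({x: -X, y: -Y, z: -Z}) * (-1) ** l2 / (FISCHER[l1] * FISCHER[l2])
                    # g = P(X,Y,Z) / r^(2L+1); extract the numerator polynomial
                    num = sp.cancel(sp.together(g) * (X**2 + Y**2 + Z**2) ** sp.Rational(2 * L + 1, 2))
                    num = sp.expand(num)
                    code = poly_to_code(num, (X, Y, Z), 2 * L)
                    code = code.replace(repr(1.0) + "*", "")
                    w(f"    T[..., {i}, {j}] = ({code}) * inv\n")
            w("    return T\n\n\n")
    w("T_BLOCKS = {\n")
    for key, fname in block_names.items():
        w(f"    {key}: {fname},\n")
    w("}\n")


if __name__ == "__main__":
    main()
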