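"""Generated by scripts/generate_tensor_tables.py -- do not edit by hand.

Real regular solid harmonics (Racah normalization, canonical component
order Q00, Q10, Q11c, Q11s, ..., Q44s) and rank-pair electrostatic
interaction tensors for the quadrupole-quadrupole (L=5) truncation.
"""
import numpy as np

COMPONENT_NAMES = [
    'Q00', 'Q10', 'Q11c', 'Q11s', 'Q20', 'Q21c', 'Q21s', 'Q22c', 'Q22s', 'Q30', 'Q31c', 'Q31s', 'Q32c', 'Q32s', 'Q33c', 'Q33s', 'Q40', 'Q41c', 'Q41s', 'Q42c', 'Q42s', 'Q43c', 'Q43s', 'Q44c', 'Q44s',
]

RANK_SLICES = {0: slice(0, 1), 1: slice(1, 4), 2: slice(4, 9), 3: slice(9, 16), 4: slice(16, 25)}

def solid_harmonics(xyz):
    """Evaluate the 25 real solid harmonics at Cartesian points.

    xyz: array (..., 3).  Returns array (..., 25) in canonical order.
    """
    xyz = np.asarray(xyz, dtype=float)
    x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    out = np.empty(xyz.shape[:-1] + (25,), dtype=float)
    out[..., 0] = 1.0
    out[..., 1] = z
    out[..., 2] = x
    out[..., 3] = y
    out[..., 4] = -0.5*x**2 + -0.5*y**2 + z**2
    out[..., 5] = 1.7320508075688772*x*z
    out[..., 6] = 1.7320508075688772*y*z
    out[..., 7] = 0.8660254037844386*x**2 + -0.8660254037844386*y**2
    out[..., 8] = 1.7320508075688772*x*y
    out[..., 9] = -1.5*x**2*z + -1.5*y**2*z + z**3
    out[..., 10] = -0.6123724356957945*x**3 + -0.6123724356957945*x*y**2 + 2.449489742783178*x*z**2
    out[..., 11] = -0.6123724356957945*x**2*y + -0.6123724356957945*y**3 + 2.449489742783178*y*z**2
    out[..., 12] = 1.9364916731037085*x**2*z + -1.9364916731037085*y**2*z
    out[..., 13] = 3.872983346207417*x*y*z
    out[..., 14] = 0.7905694150420949*x**3 + -2.3717082451262845*x*y**2
    out[..., 15] = 2.3717082451262845*x**2*y + -0.7905694150420949*y**3
    out[..., 16] = 0.375*x**4 + 0.75*x**2*y**2 + -3.0*x**2*z**2 + 0.375*y**4 + -3.0*y**2*z**2 + z**4
    out[..., 17] = -2.3717082451262845*x**3*z + -2.3717082451262845*x*y**2*z + 3.1622776601683795*x*z**3
    out[..., 18] = -2.3717082451262845*x**2*y*z + -2.3717082451262845*y**3*z + 3.1622776601683795*y*z**3
    out[..., 19] = -0.5590169943749475*x**4 + 3.3541019662496847*x**2*z**2 + 0.5590169943749475*y**4 + -3.3541019662496847*y**2*z**2
    out[..., 20] = -1.118033988749895*x**3*y + -1.118033988749895*x*y**3 + 6.708203932499369*x*y*z**2
    out[..., 21] = 2.091650066335189*x**3*z + -6.274950199005566*x*y**2*z
    out[..., 22] = 6.274950199005566*x**2*y*z + -2.091650066335189*y**3*z
    out[..., 23] = 0.739509972887452*x**4 + -4.437059837324712*x**2*y**2 + 0.739509972887452*y**4
    out[..., 24] = 2.958039891549808*x**3*y + -2.958039891549808*x*y**3
    return out


def _r_powers(X, Y, Z):
    r2 = X * X + Y * Y + Z * Z
    r = np.sqrt(r2)
    return r2, r


def _t_00(X, Y, Z):
    r2, r = _r_powers(X, Y, Z)
    inv = 1.0 / (r2**0 * r)
    T = np.empty(np.shape(X) + (1, 1), dtype=float)
    T[..., 0, 0] = (1.0) * inv
    return T


def _t_01(X, Y, Z):
    r2, r = _r_powers(X, Y, Z)
    inv = 1.0 / (r2**1 * r)
    T = np.empty(np.shape(X) + (1, 3), dtype=float)
    T[..., 0, 0] = (-Z) * inv
    T[..., 0, 1] = (-X) * inv
    T[..., 0, 2] = (-Y) * inv
    return T


def _t_02(X, Y, Z):
    r2, r = _r_powers(X, Y, Z)
    inv = 1.0 / (r2**2 * r)
    T = np.empty(np.shape(X) + (1, 5), dtype=float)
    T[..., 0, 0] = (-0.5*X**2 + -0.5*Y**2 + Z**2) * inv
    T[..., 0, 1] = (1.7320508075688772*X*Z) * inv
    T[..., 0, 2] = (1.7320508075688772*Y*Z) * inv
    T[..., 0, 3] = (0.8660254037844386*X**2 + -0.8660254037844386*Y**2) * inv
    T[..., 0, 4] = (1.7320508075688772*X*Y) * inv
    return T


def _t_03(X, Y, Z):
    r2, r = _r_powers(X, Y, Z)
    inv = 1.0 / (r2**3 * r)
    T = np.empty(np.shape(X) + (1, 7), dtype=float)
    T[..., 0, 0] = (1.5*X**2*Z + 1.5*Y**2*Z + -Z**3) * inv
    T[..., 0, 1] = (0.6123724356957945*X**3 + 0.6123724356957945*X*Y**2 + -2.449489742783178*X*Z**2) * inv
    T[..., 0, 2] = (0.6123724356957945*X**2*Y + 0.6123724356957945*Y**3 + -2.449489742783178*Y*Z**2) * inv
    T[..., 0, 3] = (-1.9364916731037085*X**2*Z + 1.9364916731037085*Y**2*Z) * inv
    T[..., 0, 4] = (-3.872983346207417*X*Y*Z) * inv
    T[..., 0, 5] = (-0.7905694150420949*X**3 + 2.3717082451262845*X*Y**2) * inv
    T[..., 0, 6] = (-2.3717082451262845*X**2*Y + 0.7905694150420949*Y**3) * inv
    return T


def _t_04(X, Y, Z):
    r2, r = _r_powers(X, Y, Z)
    inv = 1.0 / (r2**4 * r)
    T = np.empty(np.shape(X) + (1, 9), dtype=float)
    T[..., 0, 0] = (0.375*X**4 + 0.75*X**2*Y**2 + -3.0*X**2*Z**2 + 0.375*Y**4 + -3.0*Y**2*Z**2 + Z**4) * inv
    T[..., 0, 1] = (-2.3717082451262845*X**3*Z + -2.3717082451262845*X*Y**2*Z + 3.1622776601683795*X*Z**3) * inv
    T[..., 0, 2] = (-2.3717082451262845*X**2*Y*Z + -2.3717082451262845*Y**3*Z + 3.1622776601683795*Y*Z**3) * inv
    T[..., 0, 3] = (-0.5590169943749475*X**4 + 3.3541019662496847*X**2*Z**2 + 0.5590169943749475*Y**4 + -3.3541019662496847*Y**2*Z**2) * inv
    T[..., 0, 4] = (-1.118033988749895*X**3*Y + -1.118033988749895*X*Y**3 + 6.708203932499369*X*Y*Z**2) * inv
    T[..., 0, 5] = (2.091650066335189*X**3*Z + -6.274950199005566*X*Y**2*Z) * inv
    T[..., 0, 6] = (6.274950199005566*X**2*Y*Z + -2.091650066335189*Y**3*Z) * inv
    T[..., 0, 7] = (0.739509972887452*X**4 + -4.437059837324712*X**2*Y**2 + 0.739509972887452*Y**4) * inv
    T[..., 0, 8] = (2.958039891549808*X**3*Y + -2.958039891549808*X*Y**3) * inv
    return T


def _t_10(X, Y, Z):
    r2, r = _r_powers(X, Y, Z)
    inv = 1.0 / (r2**1 * r)
    T = np.empty(np.shape(X) + (3, 1), dtype=float)
    T[..., 0, 0] = (Z) * inv
    T[..., 1, 0] = (X) * inv
    T[..., 2, 0] = (Y) * inv
    return T


def _t_11(X, Y, Z):
    r2, r = _r_powers(X, Y, Z)
    inv = 1.0 / (r2**2 * r)
    T = np.empty(np.shape(X) + (3, 3), dtype=float)
    T[..., 0, 0] = (X**2 + Y**2 + -2.0*Z**2) * inv
    T[..., 0, 1] = (-3.0*X*Z) * inv
    T[..., 0, 2] = (-3.0*Y*Z) * inv
    T[..., 1, 0] = (-3.0*X*Z) * inv
    T[..., 1, 1] = (-2.0*X**2 + Y**2 + Z**2) * inv
    T[..., 1, 2] = (-3.0*X*Y) * inv
    T[..., 2, 0] = (-3.0*Y*Z) * inv
    T[..., 2, 1] = (-3.0*X*Y) * inv
    T[..., 2, 2] = (X**2 + -2.0*Y**2 + Z**2) * inv
    return T


def _t_12(X, Y, Z):
    r2, r = _r_powers(X, Y, Z)
    inv = 1.0 / (r2**3 * r)
    T = np.empty(np.shape(X) + (3, 5), dtype=float)
    T[..., 0, 0] = (-4.5*X**2*Z + -4.5*Y**2*Z + 3.0*Z**3) * inv
    T[..., 0, 1] = (-1.7320508075688772*X**3 + -1.7320508075688772*X*Y**2 + 6.928203230275509*X*Z**2) * inv
    T[..., 0, 2] = (-1.7320508075688772*X**2*Y + -1.7320508075688772*Y**3 + 6.928203230275509*Y*Z**2) * inv
    T[..., 0, 3] = (4.330127018922194*X**2*Z + -4.330127018922194*Y**2*Z) * inv
    T[..., 0, 4] = (8.660254037844387*X*Y*Z) * inv
    T[..., 1, 0] = (-1.5*X**3 + -1.5*X*Y**2 + 6.0*X*Z**2) * inv
    T[..., 1, 1] = (6.928203230275509*X**2*Z + -1.7320508075688772*Y**2*Z + -1.7320508075688772*Z**3) * inv
    T[..., 1, 2] = (8.660254037844387*X*Y*Z) * inv
    T[..., 1, 3] = (2.598076211353316*X**3 + -6.06217782649107*X*Y**2 + -1.7320508075688772*X*Z**2) * inv
    T[..., 1, 4] = (6.928203230275509*X**2*Y + -1.7320508075688772*Y**3 + -1.7320508075688772*Y*Z**2) * inv
    T[..., 2, 0] = (-1.5*X**2*Y + -1.5*Y**3 + 6.0*Y*Z**2) * inv
    T[..., 2, 1] = (8.660254037844387*X*Y*Z) * inv
    T[..., 2, 2] = (-1.7320508075688772*X**2*Z + 6.928203230275509*Y**2*Z + -1.7320508075688772*Z**3) * inv
    T[..., 2, 3] = (6.06217782649107*X**2*Y + -2.598076211353316*Y**3 + 1.7320508075688772*Y*Z**2) * inv
    T[..., 2, 4] = (-1.7320508075688772*X**3 + 6.928203230275509*X*Y**2 + -1.7320508075688772*X*Z**2) * inv
    return T


def _t_13(X, Y, Z):
    r2, r = _r_powers(X, Y, Z)
    inv = 1.0 / (r2**4 * r)
    T = np.empty(np.shape(X) + (3, 7), dtype=float)
    T[..., 0, 0] = (-1.5*X**4 + -3.0*X**2*Y**2 + 12.0*X**2*Z**2 + -1.5*Y**4 + 12.0*Y**2*Z**2 + -4.0*Z**4) * inv
    T[..., 0, 1] = (9.185586535436919*X**3*Z + 9.185586535436919*X*Y**2*Z + -12.24744871391589*X*Z**3) * inv
    T[..., 0, 2] = (9.185586535436919*X**2*Y*Z + 9.185586535436919*Y**3*Z + -12.24744871391589*Y*Z**3) * inv
    T[..., 0, 3] = (1.9364916731037085*X**4 + -11.61895003862225*X**2*Z**2 + -1.9364916731037085*Y**4 + 11.61895003862225*Y**2*Z**2) * inv
    T[..., 0, 4] = (3.872983346207417*X**3*Y + 3.872983346207417*X*Y**3 + -23.2379000772445*X*Y*Z**2) * inv
    T[..., 0, 5] = (-5.533985905294664*X**3*Z + 16.60195771588399*X*Y**2*Z) * inv
    T[..., 0, 6] = (-16.60195771588399*X**2*Y*Z + 5.533985905294664*Y**3*Z) * inv
    T[..., 1, 0] = (7.5*X**3*Z + 7.5*X*Y**2*Z + -10.0*X*Z**3) * inv
    T[..., 1, 1] = (2.449489742783178*X**4 + 1.8371173070873836*X**2*Y**2 + -16.53405576378645*X**2*Z**2 + -0.6123724356957945*Y**4 + 1.8371173070873836*Y**2*Z**2 + 2.449489742783178*Z**4) * inv
    T[..., 1, 2] = (3.0618621784789726*X**3*Y + 3.0618621784789726*X*Y**3 + -18.371173070873837*X*Y*Z**2) * inv
    T[..., 1, 3] = (-9.682458365518542*X**3*Z + 17.428425057933374*X*Y**2*Z + 3.872983346207417*X*Z**3) * inv
    T[..., 1, 4] = (-23.2379000772445*X**2*Y*Z + 3.872983346207417*Y**3*Z + 3.872983346207417*Y*Z**3) * inv
    T[..., 1, 5] = (-3.1622776601683795*X**4 + 16.60195771588399*X**2*Y**2 + 2.3717082451262845*X**2*Z**2 + -2.3717082451262845*Y**4 + -2.3717082451262845*Y**2*Z**2) * inv
    T[..., 1, 6] = (-11.858541225631422*X**3*Y + 10.277402395547233*X*Y**3 + 4.743416490252569*X*Y*Z**2) * inv
    T[..., 2, 0] = (7.5*X**2*Y*Z + 7.5*Y**3*Z + -10.0*Y*Z**3) * inv
    T[..., 2, 1] = (3.0618621784789726*X**3*Y + 3.0618621784789726*X*Y**3 + -18.371173070873837*X*Y*Z**2) * inv
    T[..., 2, 2] = (-0.6123724356957945*X**4 + 1.8371173070873836*X**2*Y**2 + 1.8371173070873836*X**2*Z**2 + 2.449489742783178*Y**4 + -16.53405576378645*Y**2*Z**2 + 2.449489742783178*Z**4) * inv
    T[..., 2, 3] = (-17.428425057933374*X**2*Y*Z + 9.682458365518542*Y**3*Z + -3.872983346207417*Y*Z**3) * inv
    T[..., 2, 4] = (3.872983346207417*X**3*Z + -23.2379000772445*X*Y**2*Z + 3.872983346207417*X*Z**3) * inv
    T[..., 2, 5] = (-10.277402395547233*X**3*Y + 11.858541225631422*X*Y**3 + -4.743416490252569*X*Y*Z**2) * inv
    T[..., 2, 6] = (2.3717082451262845*X**4 + -16.60195771588399*X**2*Y**2 + 2.3717082451262845*X**2*Z**2 + 3.1622776601683795*Y**4 + -2.3717082451262845*Y**2*Z**2) * inv
    return T


def _t_20(X, Y, Z):
    r2, r = _r_powers(X, Y, Z)
    inv = 1.0 / (r2**2 * r)
    T = np.empty(np.shape(X) + (5, 1), dtype=float)
    T[..., 0, 0] = (-0.5*X**2 + -0.5*Y**2 + Z**2) * inv
    T[..., 1, 0] = (1.7320508075688772*X*Z) * inv
    T[..., 2, 0] = (1.7320508075688772*Y*Z) * inv
    T[..., 3, 0] = (0.8660254037844386*X**2 + -0.8660254037844386*Y**2) * inv
    T[..., 4, 0] = (1.7320508075688772*X*Y) * inv
    return T


def _t_21(X, Y, Z):
    r2, r = _r_powers(X, Y, Z)
    inv = 1.0 / (r2**3 * r)
    T = np.empty(np.shape(X) + (5, 3), dtype=float)
    T[..., 0, 0] = (4.5*X**2*Z + 4.5*Y**2*Z + -3.0*Z**3) * inv
    T[..., 0, 1] = (1.5*X**3 + 1.5*X*Y**2 + -6.0*X*Z**2) * inv
    T[..., 0, 2] = (1.5*X**2*Y + 1.5*Y**3 + -6.0*Y*Z**2) * inv
    T[..., 1, 0] = (1.7320508075688772*X**3 + 1.7320508075688772*X*Y**2 + -6.928203230275509*X*Z**2) * inv
    T[..., 1, 1] = (-6.928203230275509*X**2*Z + 1.7320508075688772*Y**2*Z + 1.7320508075688772*Z**3) * inv
    T[..., 1, 2] = (-8.660254037844387*X*Y*Z) * inv
    T[..., 2, 0] = (1.7320508075688772*X**2*Y + 1.7320508075688772*Y**3 + -6.928203230275509*Y*Z**2) * inv
    T[..., 2, 1] = (-8.660254037844387*X*Y*Z) * inv
    T[..., 2, 2] = (1.7320508075688772*X**2*Z + -6.928203230275509*Y**2*Z + 1.7320508075688772*Z**3) * inv
    T[..., 3, 0] = (-4.330127018922194*X**2*Z + 4.330127018922194*Y**2*Z) * inv
    T[..., 3, 1] = (-2.598076211353316*X**3 + 6.06217782649107*X*Y**2 + 1.7320508075688772*X*Z**2) * inv
    T[..., 3, 2] = (-6.06217782649107*X**2*Y + 2.598076211353316*Y**3 + -1.7320508075688772*Y*Z**2) * inv
    T[..., 4, 0] = (-8.660254037844387*X*Y*Z) * inv
    T[..., 4, 1] = (-6.928203230275509*X**2*Y + 1.7320508075688772*Y**3 + 1.7320508075688772*Y*Z**2) * inv
    T[..., 4, 2] = (1.7320508075688772*X**3 + -6.928203230275509*X*Y**2 + 1.7320508075688772*X*Z**2) * inv
    return T


def _t_22(X, Y, Z):
    r2, r = _r_powers(X, Y, Z)
    inv = 1.0 / (r2**4 * r)
    T = np.empty(np.shape(X) + (5, 5), dtype=float)
    T[..., 0, 0] = (2.25*X**4 + 4.5*X**2*Y**2 + -18.0*X**2*Z**2 + 2.25*Y**4 + -18.0*Y**2*Z**2 + 6.0*Z**4) * inv
    T[..., 0, 1] = (-12.99038105676658*X**3*Z + -12.99038105676658*X*Y**2*Z + 17.320508075688775*X*Z**3) * inv
    T[..., 0, 2] = (-12.99038105676658*X**2*Y*Z + -12.99038105676658*Y**3*Z + 17.320508075688775*Y*Z**3) * inv
    T[..., 0, 3] = (-2.165063509461097*X**4 + 12.99038105676658*X**2*Z**2 + 2.165063509461097*Y**4 + -12.99038105676658*Y**2*Z**2) * inv
    T[..., 0, 4] = (-4.330127018922194*X**3*Y + -4.330127018922194*X*Y**3 + 25.98076211353316*X*Y*Z**2) * inv
    T[..., 1, 0] = (-12.99038105676658*X**3*Z + -12.99038105676658*X*Y**2*Z + 17.320508075688775*X*Z**3) * inv
    T[..., 1, 1] = (-4.0*X**4 + -3.0*X**2*Y**2 + 27.0*X**2*Z**2 + Y**4 + -3.0*Y**2*Z**2 + -4.0*Z**4) * inv
    T[..., 1, 2] = (-5.0*X**3*Y + -5.0*X*Y**3 + 30.0*X*Y*Z**2) * inv
    T[..., 1, 3] = (12.5*X**3*Z + -22.5*X*Y**2*Z + -5.0*X*Z**3) * inv
    T[..., 1, 4] = (30.0*X**2*Y*Z + -5.0*Y**3*Z + -5.0*Y*Z**3) * inv
    T[..., 2, 0] = (-12.99038105676658*X**2*Y*Z + -12.99038105676658*Y**3*Z + 17.320508075688775*Y*Z**3) * inv
    T[..., 2, 1] = (-5.0*X**3*Y + -5.0*X*Y**3 + 30.0*X*Y*Z**2) * inv
    T[..., 2, 2] = (X**4 + -3.0*X**2*Y**2 + -3.0*X**2*Z**2 + -4.0*Y**4 + 27.0*Y**2*Z**2 + -4.0*Z**4) * inv
    T[..., 2, 3] = (22.5*X**2*Y*Z + -12.5*Y**3*Z + 5.0*Y*Z**3) * inv
    T[..., 2, 4] = (-5.0*X**3*Z + 30.0*X*Y**2*Z + -5.0*X*Z**3) * inv
    T[..., 3, 0] = (-2.165063509461097*X**4 + 12.99038105676658*X**2*Z**2 + 2.165063509461097*Y**4 + -12.99038105676658*Y**2*Z**2) * inv
    T[..., 3, 1] = (12.5*X**3*Z + -22.5*X*Y**2*Z + -5.0*X*Z**3) * inv
    T[..., 3, 2] = (22.5*X**2*Y*Z + -12.5*Y**3*Z + 5.0*Y*Z**3) * inv
    T[..., 3, 3] = (4.75*X**4 + -25.5*X**2*Y**2 + -3.0*X**2*Z**2 + 4.75*Y**4 + -3.0*Y**2*Z**2 + Z**4) * inv
    T[..., 3, 4] = (17.5*X**3*Y + -17.5*X*Y**3) * inv
    T[..., 4, 0] = (-4.330127018922194*X**3*Y + -4.330127018922194*X*Y**3 + 25.98076211353316*X*Y*Z**2) * inv
    T[..., 4, 1] = (30.0*X**2*Y*Z + -5.0*Y**3*Z + -5.0*Y*Z**3) * inv
    T[..., 4, 2] = (-5.0*X**3*Z + 30.0*X*Y**2*Z + -5.0*X*Z**3) * inv
    T[..., 4, 3] = (17.5*X**3*Y + -17.5*X*Y**3) * inv
    T[..., 4, 4] = (-4.0*X**4 + 27.0*X**2*Y**2 + -3.0*X**2*Z**2 + -4.0*Y**4 + -3.0*Y**2*Z**2 + Z**4) * inv
    return T


def _t_30(X, Y, Z):
    r2, r = _r_powers(X, Y, Z)
    inv = 1.0 / (r2**3 * r)
    T = np.empty(np.shape(X) + (7, 1), dtype=float)
    T[..., 0, 0] = (-1.5*X**2*Z + -1.5*Y**2*Z + Z**3) * inv
    T[..., 1, 0] = (-0.6123724356957945*X**3 + -0.6123724356957945*X*Y**2 + 2.449489742783178*X*Z**2) * inv
    T[..., 2, 0] = (-0.6123724356957945*X**2*Y + -0.6123724356957945*Y**3 + 2.449489742783178*Y*Z**2) * inv
    T[..., 3, 0] = (1.9364916731037085*X**2*Z + -1.9364916731037085*Y**2*Z) * inv
    T[..., 4, 0] = (3.872983346207417*X*Y*Z) * inv
    T[..., 5, 0] = (0.7905694150420949*X**3 + -2.3717082451262845*X*Y**2) * inv
    T[..., 6, 0] = (2.3717082451262845*X**2*Y + -0.7905694150420949*Y**3) * inv
    return T


def _t_31(X, Y, Z):
    r2, r = _r_powers(X, Y, Z)
    inv = 1.0 / (r2**4 * r)
    T = np.empty(np.shape(X) + (7, 3), dtype=float)
    T[..., 0, 0] = (-1.5*X**4 + -3.0*X**2*Y**2 + 12.0*X**2*Z**2 + -1.5*Y**4 + 12.0*Y**2*Z**2 + -4.0*Z**4) * inv
    T[..., 0, 1] = (7.5*X**3*Z + 7.5*X*Y**2*Z + -10.0*X*Z**3) * inv
    T[..., 0, 2] = (7.5*X**2*Y*Z + 7.5*Y**3*Z + -10.0*Y*Z**3) * inv
    T[..., 1, 0] = (9.185586535436919*X**3*Z + 9.185586535436919*X*Y**2*Z + -12.24744871391589*X*Z**3) * inv
    T[..., 1, 1] = (2.449489742783178*X**4 + 1.8371173070873836*X**2*Y**2 + -16.53405576378645*X**2*Z**2 + -0.6123724356957945*Y**4 + 1.8371173070873836*Y**2*Z**2 + 2.449489742783178*Z**4) * inv
    T[..., 1, 2] = (3.0618621784789726*X**3*Y + 3.0618621784789726*X*Y**3 + -18.371173070873837*X*Y*Z**2) * inv
    T[..., 2, 0] = (9.185586535436919*X**2*Y*Z + 9.185586535436919*Y**3*Z + -12.24744871391589*Y*Z**3) * inv
    T[..., 2, 1] = (3.0618621784789726*X**3*Y + 3.0618621784789726*X*Y**3 + -18.371173070873837*X*Y*Z**2) * inv
    T[..., 2, 2] = (-0.6123724356957945*X**4 + 1.8371173070873836*X**2*Y**2 + 1.8371173070873836*X**2*Z**2 + 2.449489742783178*Y**4 + -16.53405576378645*Y**2*Z**2 + 2.449489742783178*Z**4) * inv
    T[..., 3, 0] = (1.9364916731037085*X**4 + -11.61895003862225*X**2*Z**2 + -1.9364916731037085*Y**4 + 11.61895003862225*Y**2*Z**2) * inv
    T[..., 3, 1] = (-9.682458365518542*X**3*Z + 17.428425057933374*X*Y**2*Z + 3.872983346207417*X*Z**3) * inv
    T[..., 3, 2] = (-17.428425057933374*X**2*Y*Z + 9.682458365518542*Y**3*Z + -3.872983346207417*Y*Z**3) * inv
    T[..., 4, 0] = (3.872983346207417*X**3*Y + 3.872983346207417*X*Y**3 + -23.2379000772445*X*Y*Z**2) * inv
    T[..., 4, 1] = (-23.2379000772445*X**2*Y*Z + 3.872983346207417*Y**3*Z + 3.872983346207417*Y*Z**3) * inv
    T[..., 4, 2] = (3.872983346207417*X**3*Z + -23.2379000772445*X*Y**2*Z + 3.872983346207417*X*Z**3) * inv
    T[..., 5, 0] = (-5.533985905294664*X**3*Z + 16.60195771588399*X*Y**2*Z) * inv
    T[..., 5, 1] = (-3.1622776601683795*X**4 + 16.60195771588399*X**2*Y**2 + 2.3717082451262845*X**2*Z**2 + -2.3717082451262845*Y**4 + -2.3717082451262845*Y**2*Z**2) * inv
    T[..., 5, 2] = (-10.277402395547233*X**3*Y + 11.858541225631422*X*Y**3 + -4.743416490252569*X*Y*Z**2) * inv
    T[..., 6, 0] = (-16.60195771588399*X**2*Y*Z + 5.533985905294664*Y**3*Z) * inv
    T[..., 6, 1] = (-11.858541225631422*X**3*Y + 10.277402395547233*X*Y**3 + 4.743416490252569*X*Y*Z**2) * inv
    T[..., 6, 2] = (2.3717082451262845*X**4 + -16.60195771588399*X**2*Y**2 + 2.3717082451262845*X**2*Z**2 + 3.1622776601683795*Y**4 + -2.3717082451262845*Y**2*Z**2) * inv
    return T


def _t_40(X, Y, Z):
    r2, r = _r_powers(X, Y, Z)
    inv = 1.0 / (r2**4 * r)
    T = np.empty(np.shape(X) + (9, 1), dtype=float)
    T[..., 0, 0] = (0.375*X**4 + 0.75*X**2*Y**2 + -3.0*X**2*Z**2 + 0.375*Y**4 + -3.0*Y**2*Z**2 + Z**4) * inv
    T[..., 1, 0] = (-2.3717082451262845*X**3*Z + -2.3717082451262845*X*Y**2*Z + 3.1622776601683795*X*Z**3) * inv
    T[..., 2, 0] = (-2.3717082451262845*X**2*Y*Z + -2.3717082451262845*Y**3*Z + 3.1622776601683795*Y*Z**3) * inv
    T[..., 3, 0] = (-0.5590169943749475*X**4 + 3.3541019662496847*X**2*Z**2 + 0.5590169943749475*Y**4 + -3.3541019662496847*Y**2*Z**2) * inv
    T[..., 4, 0] = (-1.118033988749895*X**3*Y + -1.118033988749895*X*Y**3 + 6.708203932499369*X*Y*Z**2) * inv
    T[..., 5, 0] = (2.091650066335189*X**3*Z + -6.274950199005566*X*Y**2*Z) * inv
    T[..., 6, 0] = (6.274950199005566*X**2*Y*Z + -2.091650066335189*Y**3*Z) * inv
    T[..., 7, 0] = (0.739509972887452*X**4 + -4.437059837324712*X**2*Y**2 + 0.739509972887452*Y**4) * inv
    T[..., 8, 0] = (2.958039891549808*X**3*Y + -2.958039891549808*X*Y**3) * inv
    return T


T_BLOCKS = {
    (0, 0): _t_00,
    (0, 1): _t_01,
    (0, 2): _t_02,
    (0, 3): _t_03,
    (0, 4): _t_04,
    (1, 0): _t_10,
    (1, 1): _t_11,
    (1, 2): _t_12,
    (1, 3): _t_13,
    (2, 0): _t_20,
    (2, 1): _t_21,
    (2, 2): _t_22,
    (3, 0): _t_30,
    (3, 1): _t_31,
    (4, 0): _t_40,
}
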