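"""Independent numerical oracles used by the tests.

Everything here is written from first principles (explicit shape-function
products, brute-force loops, dense algebra) so it shares no code path with
the package implementation it checks.
"""
import numpy as np

# unit-cube corner order shared with the package's documented convention
_CORNERS = [
    (0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
    (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1),
]


def _shape_grad(xi, eta, zeta):
    """Gradients of the 8 trilinear shape functions at one reference point."""
    g = np.empty((8, 3))
    for a, (cx, cy, cz) in enumerate(_CORNERS):
        sx, sy, sz = 2 * cx - 1, 2 * cy - 1, 2 * cz - 1
        fx, fy, fz = 1 + sx * xi, 1 + sy * eta, 1 + sz * zeta
        g[a] = [sx * fy * fz / 8.0, fx * sy * fz / 8.0, fx * fy * sz / 8.0]
    return g


def element_stiffness_quadrature(coords, sigma, order=4):
    """Element stiffness by explicit tensor Gauss quadrature of given order."""
    x, w = np.polynomial.legendre.leggauss(order)
    Ke = np.zeros((8, 8))
    for i in range(order):
        for j in range(order):
            for k in range(order):
                G = _shape_grad(x[i], x[j], x[k])
                J = G.T @ np.asarray(coords, dtype=float)  # d x_e / d xi_d
                det = np.linalg.det(J)
                assert det > 0
                gradx = G @ np.linalg.inv(J).T
                Ke += w[i] * w[j] * w[k] * det * (gradx @ gradx.T)
    return float(sigma) * Ke


def element_energy_quadrature(coords, sigma, u_local, order=4):
    """integral sigma |grad u|^2 over one element, u trilinear nodal."""
    x, w = np.polynomial.legendre.leggauss(order)
    e = 0.0
    for i in range(order):
        for j in range(order):
            for k in range(order):
                G = _shape_grad(x[i], x[j], x[k])
                J = G.T @ np.asarray(coords, dtype=float)
                det = np.linalg.det(J)
                gradu = (G @ np.linalg.inv(J).T).T @ np.asarray(u_local)
                e += w[i] * w[j] * w[k] * det * float(gradu @ gradu)
    return float(sigma) * e


def majority_downsample(data, factor):
    """Brute-force block majority vote (ties -> smallest label)."""
    data = np.asarray(data)
    pad = [(0, (-s) % factor) for s in data.shape]
    data = np.pad(data, pad, constant_values=0)
    out = np.zeros(tuple(s // factor for s in data.shape), dtype=data.dtype)
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            for k in range(out.shape[2]):
                block = data[
                    i * factor:(i + 1) * factor,
                    j * factor:(j + 1) * factor,
                    k * factor:(k + 1) * factor,
                ].ravel()
                vals, counts = np.unique(block, return_counts=True)
                out[i, j, k] = vals[np.argmax(counts)]
    return out


def homogeneous_sphere_potential(R, sigma, position, moment, points, n_max=400):
    """Closed-form surface potential of a dipole in a homogeneous sphere.

    Textbook Legendre form with per-degree factor (2n+1)/n; average-referenced.
    """
    x0 = np.asarray(position, float)
    m = np.asarray(moment, float)
    r0 = np.linalg.norm(x0)
    ez = x0 / r0 if r0 > 0 else m / np.linalg.norm(m)
    mr = float(m @ ez)
    mt_v = m - mr * ez
    mt = float(np.linalg.norm(mt_v))
    if mt > 0:
        ex = mt_v / mt
    else:
        a = np.array([1.0, 0, 0]) if abs(ez[0]) < 0.9 else np.array([0.0, 1, 0])
        ex = a - (a @ ez) * ez
        ex /= np.linalg.norm(ex)
    ey = np.cross(ez, ex)
    v = np.asarray(points, float)
    r = np.linalg.norm(v, axis=1)
    ct = np.clip(v @ ez / r, -1, 1)
    st = np.sqrt(1 - ct**2)
    vx, vy = v @ ex, v @ ey
    az = np.hypot(vx, vy)
    cp = np.where(az > 1e-12, vx / np.where(az > 0, az, 1.0), 0.0)
    u = np.zeros(len(v))
    P_nm1, P_n = np.ones_like(ct), ct.copy()
    for n in range(1, n_max + 1):
        Tn = np.where(st > 1e-12, n * (P_nm1 - ct * P_n) / np.where(st > 0, st, 1.0), 0.0)
        wgt = (2 * n + 1) / n * (r0 / R) ** (n - 1)
        u += wgt * (mr * n * P_n + mt * Tn * cp)
        P_nm1, P_n = P_n, ((2 * n + 1) * ct * P_n - n * P_nm1) / (n + 1)
    u /= 4 * np.pi * sigma * R**2
    return u - u.mean()
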