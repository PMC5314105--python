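"""Independent brute-force oracles used to freeze expected values.

Deliberately naive implementations (loops, explicit flood fill, closed
forms) kept separate from the library code they check.
"""

import numpy as np


def flood_fill_count(mask):
    """26-connectivity component count by explicit stack-based flood fill."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask, bool)
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
               for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    count = 0
    for start in np.argwhere(mask):
        t = tuple(start)
        if seen[t]:
            continue
        count += 1
        stack = [t]
        seen[t] = True
        while stack:
            p = stack.pop()
            for o in offsets:
                q = (p[0] + o[0], p[1] + o[1], p[2] + o[2])
                if (0 <= q[0] < mask.shape[0] and 0 <= q[1] < mask.shape[1]
                        and 0 <= q[2] < mask.shape[2]
                        and mask[q] and not seen[q]):
                    seen[q] = True
                    stack.append(q)
    return count


def sphere_voxel_count(center, radius, affine, shape):
    """Brute-force center-in-sphere membership scan over the whole grid."""
    count = 0
    for i in range(shape[0]):
        for j in range(shape[1]):
            ks = np.arange(shape[2])
            pts = (np.stack([np.full_like(ks, i), np.full_like(ks, j), ks], 1)
                   @ affine[:3, :3].T + affine[:3, 3])
            count += int(np.sum(np.linalg.norm(pts - center, axis=1) <= radius))
    return count


def line_ellipsoid_exit(entry, direction, radii):
    """Exit point of the ray entry + t*direction from an origin-centered
    ellipsoid, by the closed-form quadratic (the larger root)."""
    r = np.asarray(radii, float)
    e = np.asarray(entry, float) / r
    d = np.asarray(direction, float) / r
    a = d @ d
    b = 2 * e @ d
    c = e @ e - 1.0
    disc = b * b - 4 * a * c
    t = (-b + np.sqrt(disc)) / (2 * a)
    return np.asarray(entry) + t * np.asarray(direction)


def quaternion_rotation_between(a, b):
    """Rotation matrix taking unit vector a onto unit vector b, built from
    the half-angle quaternion."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    v = np.cross(a, b)
    w = 1.0 + a @ b
    q = np.concatenate([[w], v])
    q = q / np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def boundary_distance(mask, point, affine):
    """Distance from a world point to the nearest outside-mask voxel center,
    by exhaustive scan (the brute-force counterpart of a distance transform)."""
    out_vox = np.argwhere(~np.asarray(mask, bool))
    pts = out_vox @ affine[:3, :3].T + affine[:3, 3]
    return float(np.linalg.norm(pts - np.asarray(point, float), axis=1).min())


def closest_point_on_triangle(p, a, b, c):
    """Closest point on triangle abc to p (Ericson's algorithm)."""
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        return a + (d1 / (d1 - d3)) * ab
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        return a + (d2 / (d2 - d6)) * ac
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        return b + ((d4 - d3) / ((d4 - d3) + (d5 - d6))) * (c - b)
    denom = 1.0 / (va + vb + vc)
    return a + ab * (vb * denom) + ac * (vc * denom)


def point_mesh_distance(points, mesh, k=40):
    """Distance of each point to a triangle mesh, exact over the triangles
    touching the k nearest vertices."""
    from scipy.spatial import cKDTree
    tree = cKDTree(mesh.vertices)
    vert_faces = {}
    for fi, f in enumerate(mesh.faces):
        for v in f:
            vert_faces.setdefault(int(v), []).append(fi)
    out = []
    for p in np.atleast_2d(points):
        _, vidx = tree.query(p, k=k)
        fids = {fi for v in np.atleast_1d(vidx) for fi in vert_faces[int(v)]}
        best = np.inf
        for fi in fids:
            a, b, c = mesh.vertices[mesh.faces[fi]]
            q = closest_point_on_triangle(p, a, b, c)
            best = min(best, float(np.linalg.norm(p - q)))
        out.append(best)
    return np.asarray(out)
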