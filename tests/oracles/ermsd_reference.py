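"""Straightforward reference implementation of the eRMSD metric.

Deliberately written as plain nested loops with no shared helpers from the
package, to serve as an independent oracle for imotif.ermsd.
"""

import math

import numpy as np

SCALE = (5.0, 5.0, 3.0)
CUTOFF = 2.4


def _frame(p_c2, p_c4, p_c6):
    origin = (p_c2 + p_c4 + p_c6) / 3.0
    x = p_c2 - origin
    x = x / math.sqrt(sum(x * x))
    v = p_c4 - origin
    z = np.array([x[1] * v[2] - x[2] * v[1],
                  x[2] * v[0] - x[0] * v[2],
                  x[0] * v[1] - x[1] * v[0]])
    z = z / math.sqrt(sum(z * z))
    y = np.array([z[1] * x[2] - z[2] * x[1],
                  z[2] * x[0] - z[0] * x[2],
                  z[0] * x[1] - z[1] * x[0]])
    return origin, (x, y, z)


def _gvec(rings, j, k):
    origin_j, axes_j = _frame(*rings[j])
    origin_k, _ = _frame(*rings[k])
    rel = origin_k - origin_j
    local = [float(np.dot(axes_j[a], rel)) for a in range(3)]
    scaled = [local[a] / SCALE[a] for a in range(3)]
    rho = math.sqrt(sum(s * s for s in scaled))
    if rho >= CUTOFF:
        return [0.0, 0.0, 0.0, 0.0]
    gamma = math.pi * rho / CUTOFF
    return [math.sin(gamma) * scaled[0] / rho,
            math.sin(gamma) * scaled[1] / rho,
            math.sin(gamma) * scaled[2] / rho,
            1.0 + math.cos(gamma)]


def ermsd_reference(structure_a, structure_b, included_residues):
    """eRMSD between two structures, by direct summation."""
    def rings(structure):
        out = []
        for idx in included_residues:
            res = next(r for r in structure.residues if r.index == idx)
            out.append(tuple(np.array(res.atom(n).coords)
                             for n in ("C2", "C4", "C6")))
        return out

    ra, rb = rings(structure_a), rings(structure_b)
    n = len(included_residues)
    total = 0.0
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            ga = _gvec(ra, j, k)
            gb = _gvec(rb, j, k)
            total += sum((ga[c] - gb[c]) ** 2 for c in range(4))
    return math.sqrt(total / n)
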