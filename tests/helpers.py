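"""Test-only helpers shared across modules."""

import numpy as np


def stack_points_from(mesh, margin=0.5, step=1.0):
    """Planar cross-section point set emulating a contour stack."""
    zs = np.arange(mesh.bounds[0][2] + margin, mesh.bounds[1][2] - margin, step)
    secs = mesh.section_multiplane(plane_origin=[0, 0, 0], plane_normal=[0, 0, 1], heights=zs)
    pts = []
    for z, s in zip(zs, secs):
        if s is None:
            continue
        for e in s.entities:
            d = e.discrete(s.vertices)
            pts.append(np.column_stack([d[:, 0], d[:, 1], np.full(len(d), z)]))
    return np.vstack(pts)
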