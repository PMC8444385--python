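"""Surface reconstruction by ball pivoting, plus hole closing.

The ball-pivoting algorithm (BPA) rolls a ball of fixed radius over the
point set: wherever the ball rests on three points without containing any
other, a triangle is created; the ball then pivots around each front edge
to extend the surface. Connectivity only is created — vertices of the
output mesh are a subset of the input points. Several increasing radii are
used in sequence so that sparser regions are bridged by larger balls.

Point normals (needed to orient seed triangles and the final mesh) are
estimated by local PCA over k nearest neighbors and made consistent by
propagation along a minimum spanning tree of the neighborhood graph, then
flipped globally so the canopy (top decile of points) faces upward.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import breadth_first_order, minimum_spanning_tree
from scipy.spatial import cKDTree

from .geometry import ColoredPointCloud, GeometryError, TriangleMesh

__all__ = ["MeshingParams", "ball_pivot_mesh", "close_holes", "estimate_normals"]

log = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class MeshingParams:
    """Ball-pivoting and hole-closing parameters.

    ``ball_radii`` empty means automatic: {2, 4, 8} x the median
    nearest-neighbor distance of the input cloud. ``hole_max_boundary_edges``
    is the largest boundary-loop size (in edges) that hole closing will fill,
    following the Meshlab "max size to be closed" convention; the published
    workflow uses 50.
    """

    ball_radii: tuple[float, ...] = ()
    hole_max_boundary_edges: int = 50
    normal_k: int = 10

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.ball_radii)
        if any(r <= 0 for r in radii) or list(radii) != sorted(radii):
            raise ValueError("ball radii must be positive and increasing")
        self.ball_radii = radii


def estimate_normals(points: np.ndarray, k: int = 10) -> np.ndarray:
    """Unit normals by k-NN PCA with MST-propagated consistent orientation."""
    n = len(points)
    k = min(k, n - 1)
    tree = cKDTree(points)
    dists, nbrs = tree.query(points, k=k + 1)
    normals = np.empty((n, 3))
    for i in range(n):
        nb = points[nbrs[i]]
        nb = nb - nb.mean(axis=0)
        # smallest principal axis of the local neighborhood
        _, _, vt = np.linalg.svd(nb, full_matrices=False)
        normals[i] = vt[-1]

    # orientation consistency: MST over the k-NN graph with weight
    # 1 - |n_i . n_j|, then sign propagation from the highest point
    rows = np.repeat(np.arange(n), k)
    cols = nbrs[:, 1:].ravel()
    w = 1.0 + 1e-9 - np.abs(np.einsum("ij,ij->i", normals[rows], normals[cols]))
    g = coo_matrix((w, (rows, cols)), shape=(n, n))
    mst = minimum_spanning_tree(g)
    mst = mst + mst.T
    start = int(np.argmax(points[:, 2]))
    if normals[start, 2] < 0:
        normals[start] = -normals[start]
    order, pred = breadth_first_order(mst, start, directed=False)
    for node in order[1:]:
        p = pred[node]
        if normals[p] @ normals[node] < 0:
            normals[node] = -normals[node]

    # global flip: canopy top should face up
    top = points[:, 2] >= np.quantile(points[:, 2], 0.9)
    if normals[top, 2].mean() < 0:
        normals = -normals
    return normals


def _auto_radii(points: np.ndarray, tree: cKDTree) -> tuple[float, ...]:
    d, _ = tree.query(points, k=2)
    med = float(np.median(d[:, 1]))
    if med <= 0:
        raise GeometryError("duplicate points: cannot derive pivot radii")
    return (2 * med, 4 * med, 8 * med)


class _BallPivoter:
    """Front-based ball pivoting over a fixed point set."""

    def __init__(self, points: np.ndarray, normals: np.ndarray):
        self.pts = points
        self.normals = normals
        self.tree = cKDTree(points)
        self.faces: list[tuple[int, int, int]] = []
        self.edge_use: dict[tuple[int, int], int] = {}
        self.tri_set: set[tuple[int, int, int]] = set()
        self.used = np.zeros(len(points), dtype=bool)
        self.front: deque[tuple[int, int, int]] = deque()
        self.seed_failed = np.zeros(len(points), dtype=bool)

    # --- geometric primitives -------------------------------------------
    def _circumcenter_rows(self, pi, u, v):
        """Circumcenters of triangles (pi, pi+u, pi+v_row) for rows of v."""
        nrm = np.cross(u, v)
        nn2 = np.einsum("ij,ij->i", nrm, nrm)
        uu = float(u @ u)
        vv = np.einsum("ij,ij->i", v, v)
        with np.errstate(divide="ignore", invalid="ignore"):
            c0 = pi + (
                np.cross(nrm, u) * vv[:, None] + np.cross(v, nrm) * uu
            ) / (2 * nn2[:, None])
        return c0, nrm, nn2

    def _center(self, i: int, j: int, o: int, r: float):
        """Ball center for triangle winding (i, j, o), on its normal side."""
        pi = self.pts[i]
        u = self.pts[j] - pi
        v = (self.pts[o] - pi)[None, :]
        c0, nrm, nn2 = self._circumcenter_rows(pi, u, v)
        if nn2[0] < _EPS:
            return None
        h2 = r * r - float(np.sum((c0[0] - pi) ** 2))
        if h2 < 0:
            return None
        return c0[0] + np.sqrt(h2) * nrm[0] / np.sqrt(nn2[0])

    def _ball_empty(self, center, r, touching) -> bool:
        inside = self.tree.query_ball_point(center, r * (1 - 1e-7))
        return all(ix in touching for ix in inside)

    # --- triangle bookkeeping -------------------------------------------
    def _add_triangle(self, a: int, b: int, c: int) -> bool:
        key = tuple(sorted((a, b, c)))
        if key in self.tri_set:
            return False
        for e in ((a, b), (b, c), (c, a)):
            ekey = (min(e), max(e))
            if self.edge_use.get(ekey, 0) >= 2:
                return False
        self.tri_set.add(key)
        self.faces.append((a, b, c))
        self.used[[a, b, c]] = True
        for e, o in (((a, b), c), ((b, c), a), ((c, a), b)):
            ekey = (min(e), max(e))
            self.edge_use[ekey] = self.edge_use.get(ekey, 0) + 1
            if self.edge_use[ekey] == 1:
                self.front.append((e[0], e[1], o))
        return True

    # --- pivoting --------------------------------------------------------
    def _pivot(self, i: int, j: int, o: int, r: float):
        """Roll the ball around edge (i, j); return the first point hit."""
        pts = self.pts
        pi, pj = pts[i], pts[j]
        c_old = self._center(i, j, o, r)
        if c_old is None:
            return None
        m = 0.5 * (pi + pj)
        e = pj - pi
        elen = np.linalg.norm(e)
        if elen < _EPS:
            return None
        e = e / elen
        rho = c_old - m
        rho = rho - (rho @ e) * e
        rho_n = np.linalg.norm(rho)
        if rho_n < _EPS:
            return None
        u_old = rho / rho_n

        cand = np.array(self.tree.query_ball_point(m, rho_n + r), dtype=int)
        cand = cand[(cand != i) & (cand != j) & (cand != o)]
        if len(cand) == 0:
            return None
        u_vec = pj - pi
        v = pts[cand] - pi
        c0, nrm, nn2 = self._circumcenter_rows(pi, u_vec, v)
        ok = nn2 > _EPS * max(1.0, elen**4)
        h2 = r * r - np.einsum("ij,ij->i", c0 - pi, c0 - pi)
        ok &= h2 >= 0
        if not ok.any():
            return None
        cand, c0, nrm, nn2, h2 = cand[ok], c0[ok], nrm[ok], nn2[ok], h2[ok]
        offs = (np.sqrt(h2) / np.sqrt(nn2))[:, None] * nrm
        centers = np.concatenate([c0 + offs, c0 - offs], axis=0)
        cand2 = np.concatenate([cand, cand])

        w = centers - m
        w = w - (w @ e)[:, None] * e[None, :]
        wn = np.linalg.norm(w, axis=1)
        good = wn > _EPS
        w = np.where(good[:, None], w / np.maximum(wn, _EPS)[:, None], 0.0)
        sin_t = np.cross(np.broadcast_to(u_old, w.shape), w) @ e
        cos_t = w @ u_old
        theta = np.arctan2(sin_t, cos_t)
        # theta == 0 is legitimate: four cocircular points share one ball
        # (regular grids); only genuinely negative angles wrap around
        theta = np.where(theta < -1e-6, theta + 2 * np.pi, np.maximum(theta, 0.0))
        theta = np.where(good, theta, np.inf)

        order = np.argsort(theta)
        for idx in order[:12]:
            if not np.isfinite(theta[idx]):
                break
            x = int(cand2[idx])
            # the ball must rest on the outward side of the new triangle
            # (winding j, i, x); rejects fold-backs onto the old side when
            # four points are cocircular
            n_new = np.cross(pi - pj, pts[x] - pj)
            nn = np.linalg.norm(n_new)
            if nn < _EPS or (centers[idx] - pj) @ n_new < -1e-9 * r * nn:
                continue
            for ekey in ((min(i, x), max(i, x)), (min(j, x), max(j, x))):
                if self.edge_use.get(ekey, 0) >= 2:
                    break
            else:
                if self._ball_empty(centers[idx], r, {i, j, x}):
                    return x
        return None

    # --- seeding ---------------------------------------------------------
    def _find_seed(self, r: float):
        pts = self.pts
        for v in range(len(pts)):
            if self.used[v] or self.seed_failed[v]:
                continue
            nbrs = self.tree.query_ball_point(pts[v], 2 * r)
            nbrs = [x for x in nbrs if x != v and not self.used[x]]
            if len(nbrs) < 2:
                self.seed_failed[v] = True
                continue
            d = np.linalg.norm(pts[nbrs] - pts[v], axis=1)
            nbrs = [nbrs[t] for t in np.argsort(d)[:14]]
            n_ref = self.normals[v]
            for ai in range(len(nbrs)):
                for bi in range(ai + 1, len(nbrs)):
                    a, b = nbrs[ai], nbrs[bi]
                    tri = self._orient_seed(v, a, b, n_ref)
                    if tri is None:
                        continue
                    c = self._center(*tri, r=r)
                    if c is None or not self._ball_empty(c, r, {v, a, b}):
                        continue
                    if self._add_triangle(*tri):
                        return True
            self.seed_failed[v] = True
        return False

    def _orient_seed(self, v, a, b, n_ref):
        n_tri = np.cross(self.pts[a] - self.pts[v], self.pts[b] - self.pts[v])
        nn = np.linalg.norm(n_tri)
        if nn < _EPS:
            return None
        return (v, a, b) if n_tri @ n_ref >= 0 else (v, b, a)

    # --- driver ----------------------------------------------------------
    def run(self, r: float) -> None:
        # re-open boundary edges from a previous (smaller-radius) pass
        self.front.extend(
            (i, j, o)
            for (i, j, o) in self._boundary_triples()
        )
        self.seed_failed[:] = False
        tried: set[tuple[int, int]] = set()
        while True:
            while self.front:
                i, j, o = self.front.popleft()
                ekey = (min(i, j), max(i, j))
                if self.edge_use.get(ekey, 0) != 1 or ekey in tried:
                    continue
                tried.add(ekey)
                x = self._pivot(i, j, o, r)
                if x is not None:
                    self._add_triangle(j, i, x)
            if not self._find_seed(r):
                break

    def _boundary_triples(self):
        opp = {}
        for a, b, c in self.faces:
            for e, o in (((a, b), c), ((b, c), a), ((c, a), b)):
                opp[(min(e), max(e))] = (e[0], e[1], o)
        return [opp[k] for k, n in self.edge_use.items() if n == 1]


def ball_pivot_mesh(
    cloud: ColoredPointCloud, params: MeshingParams | None = None
) -> TriangleMesh:
    """Reconstruct a triangle mesh from a (subsampled) cloud by ball pivoting.

    Output vertices are the subset of input points referenced by at least
    one triangle; per-point colors are carried onto the mesh.
    """
    params = params or MeshingParams()
    pts = cloud.points
    if len(pts) < 3:
        raise GeometryError("ball pivoting needs at least 3 points")
    tree = cKDTree(pts)
    radii = params.ball_radii or _auto_radii(pts, tree)

    normals = estimate_normals(pts, k=params.normal_k)
    bp = _BallPivoter(pts, normals)
    for r in radii:
        bp.run(r)
    if not bp.faces:
        raise GeometryError("ball pivoting produced no triangles (collinear input?)")

    faces = np.asarray(bp.faces, dtype=np.int64)
    keep = np.unique(faces)
    remap = np.full(len(pts), -1, dtype=np.int64)
    remap[keep] = np.arange(len(keep))
    log.info(
        "ball pivoting: %d faces over %d/%d points (radii %s)",
        len(faces), len(keep), len(pts), [round(r, 3) for r in radii],
    )
    return TriangleMesh(
        vertices=pts[keep],
        faces=remap[faces],
        colors=None if cloud.colors is None else cloud.colors[keep],
    )


# ---------------------------------------------------------------------------
# hole closing
# ---------------------------------------------------------------------------


def _boundary_loops(faces: np.ndarray) -> list[list[int]]:
    use: dict[tuple[int, int], int] = {}
    directed: dict[tuple[int, int], tuple[int, int]] = {}
    for a, b, c in faces:
        for e in ((a, b), (b, c), (c, a)):
            use[(min(e), max(e))] = use.get((min(e), max(e)), 0) + 1
            directed[(e[0], e[1])] = e
    # boundary directed edges reversed so loops wind like the missing faces
    succ: dict[int, int] = {}
    for (a, b), cnt in use.items():
        if cnt != 1:
            continue
        if (a, b) in directed:
            fa, fb = a, b
        else:
            fa, fb = b, a
        if fb in succ:  # non-manifold junction: skip this loop region
            continue
        succ[fb] = fa
    loops = []
    visited: set[int] = set()
    for start in list(succ):
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        node = succ[start]
        closed = False
        while node not in visited:
            loop.append(node)
            visited.add(node)
            if node not in succ:
                break
            node = succ[node]
        else:
            closed = node == start
        if closed and len(loop) >= 3:
            loops.append(loop)
    return loops


def _ear_clip(loop: list[int], verts: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate a boundary loop on its best-fit plane by ear clipping."""
    pts3 = verts[loop]
    centroid = pts3.mean(axis=0)
    _, _, vt = np.linalg.svd(pts3 - centroid, full_matrices=False)
    plane = vt[:2]
    p2 = (pts3 - centroid) @ plane.T

    idx = list(range(len(loop)))
    # ensure CCW in the projected frame
    area2 = 0.0
    for k in range(len(idx)):
        x1, y1 = p2[idx[k]]
        x2, y2 = p2[idx[(k + 1) % len(idx)]]
        area2 += x1 * y2 - x2 * y1
    if area2 < 0:
        idx.reverse()

    tris: list[tuple[int, int, int]] = []
    guard = 0
    while len(idx) > 3 and guard < 10 * len(loop):
        guard += 1
        n_i = len(idx)
        clipped = False
        for k in range(n_i):
            a, b, c = idx[(k - 1) % n_i], idx[k], idx[(k + 1) % n_i]
            pa, pb, pc = p2[a], p2[b], p2[c]
            cr = (pb[0] - pa[0]) * (pc[1] - pa[1]) - (pb[1] - pa[1]) * (pc[0] - pa[0])
            if cr <= 1e-14:  # reflex or degenerate corner
                continue
            if any(
                _in_tri(p2[t], pa, pb, pc)
                for t in idx
                if t not in (a, b, c)
            ):
                continue
            tris.append((loop[a], loop[b], loop[c]))
            idx.pop(k)
            clipped = True
            break
        if not clipped:  # fall back to a fan; loop is nearly degenerate
            break
    if len(idx) == 3:
        tris.append((loop[idx[0]], loop[idx[1]], loop[idx[2]]))
    elif len(idx) > 3:
        for k in range(1, len(idx) - 1):
            tris.append((loop[idx[0]], loop[idx[k]], loop[idx[k + 1]]))
    return tris


def _in_tri(p, a, b, c) -> bool:
    d1 = (p[0] - b[0]) * (a[1] - b[1]) - (a[0] - b[0]) * (p[1] - b[1])
    d2 = (p[0] - c[0]) * (b[1] - c[1]) - (b[0] - c[0]) * (p[1] - c[1])
    d3 = (p[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (p[1] - a[1])
    neg = (d1 < -1e-14) or (d2 < -1e-14) or (d3 < -1e-14)
    pos = (d1 > 1e-14) or (d2 > 1e-14) or (d3 > 1e-14)
    return not (neg and pos)


def close_holes(mesh: TriangleMesh, max_boundary_edges: int = 50) -> TriangleMesh:
    """Fill every boundary loop with at most ``max_boundary_edges`` edges.

    Loops are triangulated over their own boundary vertices (no vertex is
    added); larger loops — typically the open bottom where the plant was
    cropped from the pot — are left untouched.
    """
    if mesh.n == 0:
        return mesh
    loops = _boundary_loops(mesh.faces)
    new_faces: list[tuple[int, int, int]] = []
    closed = 0
    for loop in loops:
        if len(loop) > max_boundary_edges:
            continue
        new_faces.extend(_ear_clip(loop, mesh.vertices))
        closed += 1
    if not new_faces:
        return mesh
    log.info("close_holes: filled %d of %d boundary loops", closed, len(loops))
    return TriangleMesh(
        vertices=mesh.vertices,
        faces=np.vstack([mesh.faces, np.asarray(new_faces, dtype=np.int64)]),
        colors=mesh.colors,
    )
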