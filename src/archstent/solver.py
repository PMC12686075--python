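"""Quasi-static solver for spring/beam networks.

Equilibria are found by direct minimisation of the total potential energy
(L-BFGS with analytic gradients). The structural members are:

* axial springs (bar / wire-segment stretching, EA / L0),
* angular bending springs on node triples (discrete Euler–Bernoulli bending
  of an isotropic circular section, natural turning angle theta0; torsion
  neglected),
* tension-only links (sutures),
* contact penalty terms supplied as energy/force callbacks.

Kinematic constraints are per-node 3x3 projector matrices (identity = free,
plane or line projectors, zero = fixed); minimisation is performed in the
projected displacement space, so constrained directions never move.
Convergence is declared when the projected residual-force norm falls below
``tol_rel`` times the characteristic elastic force (the largest member force
in the converged state). Accepted minimisation steps decrease the total
energy monotonically, mirroring a damped quasi-static relaxation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = ["StructuralModel", "SolverError", "RelaxationResult"]


class SolverError(RuntimeError):
    """Equilibrium search failed to reach the requested residual."""


@dataclass
class RelaxationResult:
    converged: bool
    iterations: int
    residual: float
    f_char: float
    energy: float



def _scatter(out: np.ndarray, idx: np.ndarray, vec: np.ndarray) -> None:
    """out[idx] += vec via bincount (much faster than np.add.at)."""
    n = len(out)
    for k in range(out.shape[1]):
        out[:, k] += np.bincount(idx, weights=vec[:, k], minlength=n)


class StructuralModel:
    """Assembly of nodes, elastic members, constraints and contacts."""

    def __init__(self, X0: np.ndarray):
        self.X = np.array(X0, dtype=float)
        n = len(self.X)
        self.n = n
        self._ax_ij = np.empty((0, 2), int)
        self._ax_k = np.empty(0)
        self._ax_L0 = np.empty(0)
        self._bend_abc = np.empty((0, 3), int)
        self._bend_k = np.empty(0)
        self._bend_psi0 = np.empty(0)
        self._bend_ref = np.empty((0, 3))
        self._bend_track = np.empty(0, bool)
        self._link_ij = np.empty((0, 2), int)
        self._link_kt = np.empty(0)
        self._link_kc = np.empty(0)
        self._link_L0 = np.empty(0)
        self.projectors = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
        self.contacts: list = []          # callables f(X) -> (energy, (n,3) force)
        #: additional per-node stiffness (e.g. contact penalties) folded into
        #: the Jacobi preconditioner of :meth:`relax`
        self.precond_extra = np.zeros(n)

    # ------------------------------------------------------------ assembly
    def add_axial_springs(self, pairs: np.ndarray, stiffness, rest_length) -> None:
        pairs = np.atleast_2d(np.asarray(pairs, int))
        k = np.broadcast_to(np.asarray(stiffness, float), (len(pairs),)).copy()
        L0 = np.broadcast_to(np.asarray(rest_length, float), (len(pairs),)).copy()
        self._ax_ij = np.concatenate([self._ax_ij, pairs])
        self._ax_k = np.concatenate([self._ax_k, k])
        self._ax_L0 = np.concatenate([self._ax_L0, L0])

    def add_bending(self, triples: np.ndarray, stiffness, rest_angle,
                    references: np.ndarray | None = None) -> None:
        """Angular springs: E = k/2 (theta_s - theta0)^2 with theta_s the signed
        turning angle at the middle node (0 = straight) and theta0 the natural
        turning angle.

        The sign is taken against a per-hinge reference binormal initialised
        from the current geometry, which makes concave/convex flips of a
        naturally curved wire cost energy (an unsigned angle would admit
        zero-energy zigzag modes). Call :meth:`update_bend_references` after
        each accepted load increment so the reference co-rotates with the
        material.
        """
        triples = np.atleast_2d(np.asarray(triples, int))
        k = np.broadcast_to(np.asarray(stiffness, float), (len(triples),)).copy()
        th0 = np.broadcast_to(np.asarray(rest_angle, float), (len(triples),)).copy()
        self._bend_abc = np.concatenate([self._bend_abc, triples])
        self._bend_k = np.concatenate([self._bend_k, k])
        self._bend_psi0 = np.concatenate([self._bend_psi0, np.pi - th0])
        if references is None:
            # co-rotating references, refreshed by update_bend_references
            ref = np.zeros((len(triples), 3))
            track = np.ones(len(triples), bool)
        else:
            ref = np.asarray(references, float).copy()
            ref /= np.maximum(np.linalg.norm(ref, axis=1, keepdims=True), 1e-12)
            track = np.zeros(len(triples), bool)
        self._bend_ref = np.concatenate([self._bend_ref, ref]) \
            if len(self._bend_ref) else ref
        self._bend_track = np.concatenate([getattr(self, "_bend_track",
                                                   np.empty(0, bool)), track])
        self.update_bend_references()

    def update_bend_references(self) -> None:
        """Refresh the co-rotating per-hinge reference binormals from the
        current state (hinges created with explicit references keep them)."""
        if len(self._bend_abc) == 0:
            return
        a, b, c = self._bend_abc.T
        cross = np.cross(self.X[b] - self.X[a], self.X[c] - self.X[b])
        nrm = np.linalg.norm(cross, axis=1)
        ok = (nrm > 1e-10) & self._bend_track
        self._bend_ref[ok] = cross[ok] / nrm[ok, None]

    def add_tension_links(self, pairs: np.ndarray, k_tension, rest_length,
                          k_compression=0.0) -> None:
        pairs = np.atleast_2d(np.asarray(pairs, int))
        if len(pairs) == 0:
            return
        kt = np.broadcast_to(np.asarray(k_tension, float), (len(pairs),)).copy()
        kc = np.broadcast_to(np.asarray(k_compression, float), (len(pairs),)).copy()
        L0 = np.broadcast_to(np.asarray(rest_length, float), (len(pairs),)).copy()
        self._link_ij = np.concatenate([self._link_ij, pairs])
        self._link_kt = np.concatenate([self._link_kt, kt])
        self._link_kc = np.concatenate([self._link_kc, kc])
        self._link_L0 = np.concatenate([self._link_L0, L0])

    def fix_nodes(self, idx) -> None:
        self.projectors[np.asarray(idx, int)] = 0.0

    def constrain_to_plane(self, idx, normal: np.ndarray) -> None:
        """Allow motion only in the plane perpendicular to ``normal``."""
        nrm = np.asarray(normal, float)
        nrm = nrm / np.linalg.norm(nrm)
        self.projectors[np.asarray(idx, int)] = np.eye(3) - np.outer(nrm, nrm)

    def constrain_to_line(self, idx, direction: np.ndarray) -> None:
        """Allow motion only along ``direction`` (per node if 2D array)."""
        idx = np.atleast_1d(np.asarray(idx, int))
        d = np.atleast_2d(np.asarray(direction, float))
        if len(d) == 1:
            d = np.repeat(d, len(idx), axis=0)
        d = d / np.linalg.norm(d, axis=1, keepdims=True)
        self.projectors[idx] = d[:, :, None] * d[:, None, :]

    def add_contact(self, fn) -> None:
        self.contacts.append(fn)

    # -------------------------------------------------------------- forces
    def _axial_terms(self, X: np.ndarray, out: np.ndarray) -> tuple[float, float]:
        if len(self._ax_ij) == 0:
            return 0.0, 0.0
        i, j = self._ax_ij[:, 0], self._ax_ij[:, 1]
        d = X[j] - X[i]
        L = np.maximum(np.linalg.norm(d, axis=1), 1e-12)
        f = self._ax_k * (L - self._ax_L0)
        vec = (f / L)[:, None] * d
        _scatter(out, i, vec)
        _scatter(out, j, -vec)
        E = float(0.5 * np.sum(self._ax_k * (L - self._ax_L0) ** 2))
        return E, float(np.abs(f).max(initial=0.0))

    def _bending_terms(self, X: np.ndarray, out: np.ndarray) -> tuple[float, float]:
        """Discrete-rod bending: E = (k~/2) |kb - kb0|^2 per hinge with the
        curvature binormal kb = 2 (e1 x e2) / (|e1||e2| + e1.e2) and the rest
        vector kb0 = 2 tan(theta0/2) * ref. Smooth in the node positions
        everywhere short of a complete fold; k~ is scaled so the small-
        deviation stiffness about the rest state equals the nominal k."""
        if len(self._bend_abc) == 0:
            return 0.0, 0.0
        a, b, c = self._bend_abc.T
        e1 = X[b] - X[a]
        e2 = X[c] - X[b]
        n1 = np.maximum(np.linalg.norm(e1, axis=1), 1e-12)
        n2 = np.maximum(np.linalg.norm(e2, axis=1), 1e-12)
        D = np.maximum(n1 * n2 + np.einsum("ij,ij->i", e1, e2), 1e-8 * n1 * n2)
        kb = 2.0 * np.cross(e1, e2) / D[:, None]
        theta0 = np.pi - self._bend_psi0
        kt = self._bend_k * np.cos(theta0 / 2.0) ** 4
        kb0 = (2.0 * np.tan(theta0 / 2.0))[:, None] * self._bend_ref
        dv = kb - kb0
        w = kt[:, None] * dv
        wk = np.einsum("ij,ij->i", w, kb)
        v1 = (n2 / n1)[:, None] * e1 + e2
        v2 = (n1 / n2)[:, None] * e2 + e1
        dE_de1 = (2.0 * np.cross(e2, w) - wk[:, None] * v1) / D[:, None]
        dE_de2 = (-2.0 * np.cross(e1, w) - wk[:, None] * v2) / D[:, None]
        Fa = dE_de1
        Fc = -dE_de2
        _scatter(out, a, Fa)
        _scatter(out, c, Fc)
        _scatter(out, b, -(Fa + Fc))
        E = float(0.5 * np.sum(kt * np.einsum("ij,ij->i", dv, dv)))
        f_el = np.linalg.norm(w, axis=1) / np.minimum(n1, n2)
        return E, float(f_el.max(initial=0.0))

    def _link_terms(self, X: np.ndarray, out: np.ndarray) -> tuple[float, float]:
        if len(self._link_ij) == 0:
            return 0.0, 0.0
        i, j = self._link_ij[:, 0], self._link_ij[:, 1]
        d = X[j] - X[i]
        L = np.maximum(np.linalg.norm(d, axis=1), 1e-12)
        ext = L - self._link_L0
        k = np.where(ext > 0, self._link_kt, self._link_kc)
        vec = (k * ext / L)[:, None] * d
        _scatter(out, i, vec)
        _scatter(out, j, -vec)
        E = float(0.5 * np.sum(k * ext ** 2))
        return E, float(np.abs(k * ext).max(initial=0.0))

    def evaluate(self, X: np.ndarray) -> tuple[float, np.ndarray, float]:
        """(total energy, nodal forces, characteristic member force)."""
        F = np.zeros_like(X)
        E1, c1 = self._axial_terms(X, F)
        E2, c2 = self._bending_terms(X, F)
        E3, c3 = self._link_terms(X, F)
        E = E1 + E2 + E3
        f_char = max(c1, c2, c3)
        for contact in self.contacts:
            Ec, Fc = contact(X)
            E += Ec
            F += Fc
            f_char = max(f_char, float(np.linalg.norm(Fc, axis=1).max(initial=0.0)))
        return E, F, f_char

    def internal_forces(self, X: np.ndarray | None = None) -> tuple[np.ndarray, float]:
        """Elastic nodal forces and total elastic energy (contacts excluded)."""
        X = self.X if X is None else X
        F = np.zeros_like(X)
        E1, _ = self._axial_terms(X, F)
        E2, _ = self._bending_terms(X, F)
        E3, _ = self._link_terms(X, F)
        return F, E1 + E2 + E3

    def elastic_energy(self, X: np.ndarray | None = None) -> float:
        return self.internal_forces(X)[1]

    def angles(self, X: np.ndarray | None = None) -> np.ndarray:
        """Current interior angles psi of all bending triples."""
        X = self.X if X is None else X
        a, b, c = self._bend_abc.T
        u1 = X[a] - X[b]
        u2 = X[c] - X[b]
        u1 /= np.maximum(np.linalg.norm(u1, axis=1), 1e-12)[:, None]
        u2 /= np.maximum(np.linalg.norm(u2, axis=1), 1e-12)[:, None]
        return np.arccos(np.clip(np.einsum("ij,ij->i", u1, u2), -1, 1))

    def bending_deviation(self, X: np.ndarray | None = None) -> np.ndarray:
        """Turning-angle deviation magnitude per bending triple.

        The angle-equivalent of |kb - kb0| (exact to second order around the
        rest state); used to turn hinge rotations into curvature changes.
        """
        X = self.X if X is None else X
        a, b, c = self._bend_abc.T
        e1 = X[b] - X[a]
        e2 = X[c] - X[b]
        n1 = np.maximum(np.linalg.norm(e1, axis=1), 1e-12)
        n2 = np.maximum(np.linalg.norm(e2, axis=1), 1e-12)
        D = np.maximum(n1 * n2 + np.einsum("ij,ij->i", e1, e2), 1e-8 * n1 * n2)
        kb = 2.0 * np.cross(e1, e2) / D[:, None]
        theta0 = np.pi - self._bend_psi0
        kb0 = (2.0 * np.tan(theta0 / 2.0))[:, None] * self._bend_ref
        dv = np.linalg.norm(kb - kb0, axis=1)
        return dv * np.cos(theta0 / 2.0) ** 2

    # ---------------------------------------------------------- relaxation
    def _node_stiffness_scale(self) -> np.ndarray:
        """Per-node translational stiffness estimate (Jacobi preconditioner)."""
        k_node = np.zeros(self.n)
        if len(self._ax_ij):
            np.add.at(k_node, self._ax_ij[:, 0], self._ax_k)
            np.add.at(k_node, self._ax_ij[:, 1], self._ax_k)
        if len(self._bend_abc):
            r1 = self.X[self._bend_abc[:, 0]] - self.X[self._bend_abc[:, 1]]
            L2 = np.maximum(np.einsum("ij,ij->i", r1, r1), 1e-12)
            kb_t = 4.0 * self._bend_k / L2
            for col in range(3):
                np.add.at(k_node, self._bend_abc[:, col], kb_t)
        if len(self._link_ij):
            np.add.at(k_node, self._link_ij[:, 0], self._link_kt)
            np.add.at(k_node, self._link_ij[:, 1], self._link_kt)
        k_node += self.precond_extra
        return np.maximum(k_node, 1e-9)

    def relax(self, max_iter: int = 4000, tol_rel: float = 1e-4,
              raise_on_fail: bool = True, _history: list | None = None) -> RelaxationResult:
        """Find the equilibrium from the current state (updates ``self.X``)."""
        X0 = self.X.copy()
        P = self.projectors
        shape = X0.shape
        scale = np.sqrt(self._node_stiffness_scale())[:, None]

        def objective(y: np.ndarray):
            u = np.einsum("nij,nj->ni", P, y.reshape(shape) / scale)
            X = X0 + u
            E, F, _ = self.evaluate(X)
            g = -np.einsum("nij,nj->ni", P, F) / scale
            if _history is not None:
                _history.append(E)
            return E, g.ravel()

        # L-BFGS in restart chunks: a fresh inverse-Hessian approximation lets
        # the search escape stiff valleys where a single run stalls on its own
        # termination criteria before the force residual is met.
        def descent_rescue(y: np.ndarray, n_steps: int = 60) -> tuple[np.ndarray, bool]:
            """Backtracking steepest-descent: guarantees progress while the
            gradient is nonzero, un-sticking a failed L-BFGS line search."""
            progressed = False
            E, g = objective(y)
            for _ in range(n_steps):
                gn = float(np.linalg.norm(g))
                if gn < 1e-14:
                    break
                alpha = 1.0 / gn
                ok = False
                for _ in range(40):
                    y_try = y - alpha * g
                    E_try, g_try = objective(y_try)
                    if E_try < E:
                        y, E, g = y_try, E_try, g_try
                        ok = progressed = True
                        break
                    alpha *= 0.5
                if not ok:
                    break
            return y, progressed

        y = np.zeros(X0.size)
        total_it = 0
        chunk = max(500, max_iter // 16)
        while total_it < max_iter:
            res = minimize(objective, y, jac=True, method="L-BFGS-B",
                           options={"maxiter": chunk, "ftol": 1e-16, "gtol": 1e-14,
                                    "maxcor": 30, "maxfun": 10 * chunk})
            moved = float(np.abs(res.x - y).max(initial=0.0))
            y = res.x
            total_it += max(int(res.nit), 1)
            X_try = X0 + np.einsum("nij,nj->ni", P, y.reshape(shape) / scale)
            E, F, f_char = self.evaluate(X_try)
            Fp = np.einsum("nij,nj->ni", P, F)
            resid = float(np.linalg.norm(Fp, axis=1).max(initial=0.0))
            if resid <= tol_rel * max(f_char, 1e-9):
                break
            if moved < 1e-12 and int(res.nit) <= 1:
                y, progressed = descent_rescue(y)
                total_it += 60
                if not progressed:
                    break   # fully stalled, no further progress possible
        self.X = X0 + np.einsum("nij,nj->ni", P, y.reshape(shape) / scale)
        E, F, f_char = self.evaluate(self.X)
        Fp = np.einsum("nij,nj->ni", P, F)
        resid = float(np.linalg.norm(Fp, axis=1).max(initial=0.0))
        converged = resid <= tol_rel * max(f_char, 1e-9)
        out = RelaxationResult(converged, total_it, resid, f_char, E)
        if not converged and raise_on_fail:
            raise SolverError(
                f"equilibrium search stalled after {total_it} iterations: residual "
                f"{resid:.3e} vs tolerance {tol_rel * max(f_char, 1e-9):.3e}")
        return out

    def reaction_forces(self, X: np.ndarray | None = None) -> np.ndarray:
        """Constraint reactions: the force component removed by the projectors."""
        X = self.X if X is None else X
        _, F, _ = self.evaluate(X)
        return F - np.einsum("nij,nj->ni", self.projectors, F)
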