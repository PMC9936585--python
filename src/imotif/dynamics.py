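"""Ratchet-and-pawl biased dynamics on a coarse-grained double-basin model.

This is a desk-scale surrogate of the all-atom rMD protocol: the system is
free to evolve under room-temperature fluctuations, while motion backward
along the reaction coordinate ξ = eRMSD(current, target) is penalised by a
one-sided harmonic pawl ½·k·(ξ − ξ_best)² with k = 200 kcal/mol per squared
eRMSD unit and target value 0.

Model
-----
* Beads: the three eRMSD ring atoms (C2/C4/C6) plus C1' of every residue
  shared by the two endpoint structures (thymines drop out naturally).
* Per-contact double-basin network: every inter-residue bead pair within
  a cutoff of either endpoint carries a smoothed two-well energy
  softmin(½k(d−d_S)², ½k(d−d_T)² − δ); the small per-contact offset δ makes
  the target (neutral, E) basin globally more stable, as found for the
  real molecule.
* Protonation gating: C:C+ pairing restraints on the ring-bead centroid
  distance of each protonated pair, and scenario-dependent contact wells —
  in the neutral scenario the deprotonated pairs C1:C19 and C6:C14 lose
  their start-state wells (no shared proton, no hemiprotonated H-bonds),
  while in the acidic scenario every contact of the switching cytosines is
  pinned to the start geometry (a protonated stack cannot disassemble).
* Integration: overdamped (Brownian) Langevin steps; when ξ > ξ_best the
  pawl adds the force −k·(ξ−ξ_best)·∇ξ with the exact analytic eRMSD
  gradient, and never injects energy on spontaneous descent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import kt, T_DEFAULT
from .structure import Structure
from .ermsd import SCALE_PLANE, SCALE_NORMAL, CUTOFF

__all__ = ["RatchetState", "ratchet_bias", "CGModel", "build_cg_model",
           "TransitionRun", "RatchetSimulation", "run_rmd",
           "transition_summary", "ModelError", "InstabilityError",
           "CC_PAIRS_ALL", "CC_PAIRS_PERSISTENT"]

#: hemiprotonated pairs of the acidic structure (NN4 numbering)
CC_PAIRS_ALL = ((1, 19), (2, 20), (6, 14), (7, 15))
#: pairs that stay protonated at neutral pH
CC_PAIRS_PERSISTENT = ((2, 20), (7, 15))
#: cytosines that deprotonate across the transition (monitored observables)
SWITCHING_CYTOSINES = (1, 6, 14, 19)

BEAD_ATOMS = ("C2", "C4", "C6", "C1'")


class ModelError(ValueError):
    pass


class InstabilityError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Ratchet bias (continuous form)
# ---------------------------------------------------------------------------

@dataclass
class RatchetState:
    xi: float
    xi_best: float
    k: float = 200.0

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("force constant must be >= 0")


def ratchet_bias(state: RatchetState) -> tuple[float, float]:
    """One-sided harmonic pawl.

    Returns (energy kcal/mol, restoring force along ξ); afterwards
    ``state.xi_best`` is updated to min(xi_best, xi).
    """
    dxi = state.xi - state.xi_best
    if dxi > 0:
        energy = 0.5 * state.k * dxi * dxi
        force = -state.k * dxi
    else:
        energy, force = 0.0, 0.0
    state.xi_best = min(state.xi_best, state.xi)
    return energy, force


# ---------------------------------------------------------------------------
# Coarse-grained double-basin model
# ---------------------------------------------------------------------------

@dataclass
class CGModel:
    residue_indices: list          # residues represented, in order
    bases: list                    # their base letters
    coords_start: np.ndarray       # (n_beads, 3)
    coords_target: np.ndarray
    contacts_i: np.ndarray         # bead index arrays
    contacts_j: np.ndarray
    d_start: np.ndarray
    d_target: np.ndarray
    k_contact: np.ndarray
    delta: np.ndarray              # per-contact target-basin offset
    restraints: list               # [(bead_idx_a (3,), bead_idx_b (3,), d0, k)]
    ring_index: np.ndarray         # (n_res, 3) bead indices of C2/C4/C6
    mixing_energy: float = 1.0     # kcal/mol softmin temperature
    protonation: str = "acidic"

    @property
    def n_beads(self) -> int:
        return len(self.coords_start)

    def energy_forces(self, x: np.ndarray):
        """Potential energy and forces for a batch of conformations.

        ``x``: (B, n_beads, 3); returns (energy (B,), forces (B, n_beads, 3)).
        """
        x = np.asarray(x, dtype=float)
        single = x.ndim == 2
        if single:
            x = x[None]
        B = x.shape[0]
        e = np.zeros(B)
        f = np.zeros_like(x)
        ci, cj = self.contacts_i, self.contacts_j
        dv = x[:, ci] - x[:, cj]                       # (B, C, 3)
        d = np.linalg.norm(dv, axis=-1)
        d = np.maximum(d, 1e-8)
        es = 0.5 * self.k_contact * (d - self.d_start) ** 2
        et = 0.5 * self.k_contact * (d - self.d_target) ** 2 - self.delta
        t0 = self.mixing_energy
        lo = np.minimum(es, et)
        w_t = 1.0 / (1.0 + np.exp(np.clip((et - es) / t0, -60, 60)))
        # smoothed two-well: softmin of the start/target parabolas
        e += (lo - t0 * np.log(np.exp((lo - es) / t0)
                               + np.exp((lo - et) / t0))).sum(axis=1)
        # dE/dd with softmin weights
        dedd = self.k_contact * ((1 - w_t) * (d - self.d_start)
                                 + w_t * (d - self.d_target))
        fij = -(dedd / d)[..., None] * dv              # force on bead i
        np.add.at(f, (slice(None), ci), fij)
        np.add.at(f, (slice(None), cj), -fij)
        for (ia, ib, d0, kr) in self.restraints:
            ca = x[:, ia].mean(axis=1)                 # (B, 3)
            cb = x[:, ib].mean(axis=1)
            dv_r = ca - cb
            dr = np.maximum(np.linalg.norm(dv_r, axis=-1), 1e-8)
            e += 0.5 * kr * (dr - d0) ** 2
            g = (kr * (dr - d0) / dr)[:, None] * dv_r  # dE/dca
            for idx in ia:
                f[:, idx] -= g / len(ia)
            for idx in ib:
                f[:, idx] += g / len(ib)
        return e, f


def _bead_layout(structure: Structure, residue_indices):
    coords = []
    ring_index = []
    pos = {r.index: r for r in structure.residues}
    for idx in residue_indices:
        r = pos[idx]
        start = len(coords)
        for name in BEAD_ATOMS:
            a = r.atom(name)
            if a is None:
                raise ModelError(f"residue {r.base}{idx} lacks bead atom {name}")
            coords.append(a.coords)
        ring_index.append([start, start + 1, start + 2])
    return np.array(coords), np.array(ring_index)


def build_cg_model(start: Structure, target: Structure,
                   protonation: str = "neutral",
                   contact_cutoff: float = 8.0,
                   k_contact: float = 0.1, delta: float = 0.75,
                   k_pair: float = 20.0, k_intra: float = 10.0,
                   mixing_energy: float = 1.5) -> CGModel:
    """Double-basin coarse-grained model between two endpoint structures.

    The model lives on the residues shared by both endpoints (identical
    bases required).  ``protonation`` selects which C:C+ pairing restraints
    are active: 'acidic' keeps all four, 'neutral' removes C1:C19 and
    C6:C14 (the pairs that deprotonate at pH 7).
    """
    if protonation not in ("acidic", "neutral"):
        raise ModelError(f"unknown protonation scenario {protonation!r}")
    b_start = {r.index: r.base for r in start.residues}
    b_target = {r.index: r.base for r in target.residues}
    common = sorted(set(b_start) & set(b_target))
    if not common:
        raise ModelError("structures share no residues")
    mismatch = [i for i in common if b_start[i] != b_target[i]]
    if mismatch:
        raise ModelError(f"sequence mismatch at residues {mismatch}")
    xs, ring_index = _bead_layout(start, common)
    xt, _ = _bead_layout(target, common)
    n = len(xs)
    res_of = np.repeat(np.arange(len(common)), len(BEAD_ATOMS))
    ds_all = np.linalg.norm(xs[:, None] - xs[None, :], axis=-1)
    dt_all = np.linalg.norm(xt[:, None] - xt[None, :], axis=-1)
    iu, ju = np.triu_indices(n, k=1)
    inter = res_of[iu] != res_of[ju]
    near = (ds_all[iu, ju] < contact_cutoff) | (dt_all[iu, ju] < contact_cutoff)
    sel_inter = inter & near
    sel_intra = ~inter
    ci = np.concatenate([iu[sel_inter], iu[sel_intra]])
    cj = np.concatenate([ju[sel_inter], ju[sel_intra]])
    kc = np.concatenate([np.full(sel_inter.sum(), k_contact),
                         np.full(sel_intra.sum(), k_intra)])
    dlt = np.concatenate([np.full(sel_inter.sum(), delta),
                          np.zeros(sel_intra.sum())])
    pairs = CC_PAIRS_ALL if protonation == "acidic" else CC_PAIRS_PERSISTENT
    res_pos = {idx: k for k, idx in enumerate(common)}
    d_start_c = ds_all[ci, cj].copy()
    d_target_c = dt_all[ci, cj].copy()
    switching = [res_pos[i] for i in SWITCHING_CYTOSINES if i in res_pos]
    if protonation == "neutral":
        # deprotonated pairs lose their hemiprotonated H-bonding: their
        # pair-internal contacts keep only the target-basin well
        gone = set(CC_PAIRS_ALL) - set(CC_PAIRS_PERSISTENT)
        gone_pos = {frozenset((res_pos[a], res_pos[b]))
                    for a, b in gone if a in res_pos and b in res_pos}
        for t in range(len(ci)):
            key = frozenset((int(res_of[ci[t]]), int(res_of[cj[t]])))
            if key in gone_pos:
                d_start_c[t] = dt_all[ci[t], cj[t]]
    else:
        # while protonated, the C:C+ stack cannot disassemble: every
        # contact of a switching cytosine keeps the start-state geometry
        sw = set(switching)
        for t in range(len(ci)):
            if int(res_of[ci[t]]) in sw or int(res_of[cj[t]]) in sw:
                d_target_c[t] = ds_all[ci[t], cj[t]]
    restraints = []
    for (a, b) in pairs:
        if a not in res_pos or b not in res_pos:
            continue
        ia = ring_index[res_pos[a]]
        ib = ring_index[res_pos[b]]
        d0 = float(np.linalg.norm(xs[ia].mean(axis=0) - xs[ib].mean(axis=0)))
        restraints.append((ia, ib, d0, k_pair))
    return CGModel(residue_indices=common, bases=[b_start[i] for i in common],
                   coords_start=xs, coords_target=xt,
                   contacts_i=ci, contacts_j=cj,
                   d_start=d_start_c, d_target=d_target_c,
                   k_contact=kc, delta=dlt, restraints=restraints,
                   ring_index=ring_index, mixing_energy=mixing_energy,
                   protonation=protonation)


# ---------------------------------------------------------------------------
# Batched eRMSD on bead coordinates
# ---------------------------------------------------------------------------

def _gvec_batch(rings: np.ndarray) -> np.ndarray:
    """G-vectors for (B, N, 3, 3) batched ring coordinates -> (B, N, N, 4)."""
    origins = rings.mean(axis=2)                        # (B, N, 3)
    x = rings[:, :, 0] - origins
    x = x / np.linalg.norm(x, axis=-1, keepdims=True)
    v = rings[:, :, 1] - origins
    z = np.cross(x, v)
    z = z / np.linalg.norm(z, axis=-1, keepdims=True)
    y = np.cross(z, x)
    axes = np.stack([x, y, z], axis=2)                  # (B, N, 3, 3)
    rel = origins[:, None, :, :] - origins[:, :, None, :]
    local = np.einsum("bnxy,bnky->bnkx", axes, rel)
    scaled = local / np.array([SCALE_PLANE, SCALE_PLANE, SCALE_NORMAL])
    rho = np.linalg.norm(scaled, axis=-1)
    B, N = rho.shape[0], rho.shape[1]
    rho[:, np.arange(N), np.arange(N)] = np.inf
    inside = rho < CUTOFF
    gamma = np.where(inside, np.pi * rho / CUTOFF, np.pi)
    with np.errstate(invalid="ignore", divide="ignore"):
        radial = np.where(inside[..., None],
                          np.sin(gamma)[..., None] * scaled / rho[..., None],
                          0.0)
    fourth = np.where(inside, 1.0 + np.cos(gamma), 0.0)
    return np.concatenate([radial, fourth[..., None]], axis=-1)


def _ermsd_batch(rings: np.ndarray, g_ref: np.ndarray) -> np.ndarray:
    g = _gvec_batch(rings)
    n = rings.shape[1]
    return np.sqrt(((g - g_ref[None]) ** 2).sum(axis=(1, 2, 3)) / n)


def _ermsd_grad_batch(rings: np.ndarray, g_ref: np.ndarray):
    """ξ and its full analytic gradient with respect to the ring atoms.

    Differentiates the G-vectors through both the relative base origins and
    the base frames (x̂ from C2, ẑ from the ring normal), so the bias force
    can translate and reorient bases.

    Returns (xi (B,), grad (B, N, 3, 3)) — per base, per ring atom.
    """
    scale = np.array([SCALE_PLANE, SCALE_PLANE, SCALE_NORMAL])
    origins = rings.mean(axis=2)
    x = rings[:, :, 0] - origins
    x = x / np.linalg.norm(x, axis=-1, keepdims=True)
    v = rings[:, :, 1] - origins
    z = np.cross(x, v)
    z = z / np.linalg.norm(z, axis=-1, keepdims=True)
    y = np.cross(z, x)
    axes = np.stack([x, y, z], axis=2)                  # (B, N, 3, 3)
    rel = origins[:, None, :, :] - origins[:, :, None, :]
    scaled = np.einsum("bjxy,bjky->bjkx", axes, rel) / scale
    rho = np.linalg.norm(scaled, axis=-1)
    B, N = rho.shape[:2]
    rho[:, np.arange(N), np.arange(N)] = np.inf
    inside = rho < CUTOFF
    gamma = np.where(inside, np.pi * rho / CUTOFF, np.pi)
    sin_g, cos_g = np.sin(gamma), np.cos(gamma)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(inside[..., None], scaled / rho[..., None], 0.0)
    radial = sin_g[..., None] * unit
    fourth = np.where(inside, 1.0 + cos_g, 0.0)
    g = np.concatenate([radial, fourth[..., None]], axis=-1)
    dg = g - g_ref[None]
    n = N
    xi = np.sqrt((dg ** 2).sum(axis=(1, 2, 3)) / n)
    # v_jk = (dF/dr̃)^T · ΔG for in-range pairs
    dgr = dg[..., :3]                                   # radial components
    dgw = dg[..., 3]                                    # fourth component
    rho_s = np.where(inside, rho, 1.0)
    dot_ru = (dgr * unit).sum(axis=-1)
    pref = np.pi / CUTOFF
    v = (sin_g / rho_s)[..., None] * dgr \
        + ((cos_g * pref - sin_g / rho_s) * dot_ru
           - sin_g * pref * dgw)[..., None] * unit
    v = np.where(inside[..., None], v, 0.0)
    vs = v / scale                                       # ∂Φ/∂l, l = A_j(o_k−o_j)
    # translational part: ∂l/∂o_k = A_j, ∂l/∂o_j = −A_j
    w = np.einsum("bjkx,bjxy->bjky", vs, axes)           # (B, j, k, 3)
    g_origin = w.sum(axis=1) - w.sum(axis=2)             # d/do_k − d/do_j
    # rotational part: ∂Φ/∂A_j = Σ_k vs ⊗ (o_k − o_j), then through the
    # frame construction x̂ = (p1−o)/|·|, ẑ = x̂×(p2−o)/|·|, ŷ = ẑ×x̂
    M = np.einsum("bjkx,bjky->bjxy", vs, rel)            # (B, N, 3, 3) rows x,y,z
    a_vec = rings[:, :, 0] - origins
    alpha = np.linalg.norm(a_vec, axis=-1, keepdims=True)
    b_vec = rings[:, :, 1] - origins
    c_vec = np.cross(x, b_vec)
    gamma_n = np.linalg.norm(c_vec, axis=-1, keepdims=True)
    m_x = M[:, :, 0] + np.cross(M[:, :, 1], z)
    m_z = M[:, :, 2] + np.cross(x, M[:, :, 1])
    q = (m_z - (m_z * z).sum(-1, keepdims=True) * z) / gamma_n
    m_x = m_x + np.cross(b_vec, q)
    m_b = np.cross(q, x)
    m_a = (m_x - (m_x * x).sum(-1, keepdims=True) * x) / alpha
    grad = np.zeros_like(rings)                          # (B, N, 3 atoms, 3)
    grad[:, :, 0] += m_a
    grad[:, :, 1] += m_b
    grad -= ((m_a + m_b) / 3.0)[:, :, None, :]
    grad += (g_origin / 3.0)[:, :, None, :]
    denom = np.maximum(xi, 1e-12) * n
    return xi, grad / denom[:, None, None, None]


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class TransitionRun:
    scenario: str
    seeds: list
    n_steps: int
    temperature: float
    k_bias: float
    threshold: float
    xi_series: np.ndarray          # (n_traj, n_steps + 1)
    success: np.ndarray            # (n_traj,) bool
    frames: np.ndarray             # (n_traj, n_saved, n_beads, 3)
    frame_stride: int
    model: CGModel

    @property
    def success_rate(self) -> float:
        return float(np.mean(self.success))

    def summary(self) -> str:
        lines = [f"rMD surrogate run — scenario: {self.scenario}",
                 f"  trajectories: {len(self.seeds)}   steps: {self.n_steps}"
                 f"   k_bias: {self.k_bias} kcal/mol per eRMSD²",
                 f"  success threshold: {self.threshold} eRMSD units",
                 f"  xi start: {self.xi_series[0, 0]:.3f}   "
                 f"median min xi: {np.median(self.xi_series.min(axis=1)):.3f}",
                 f"  successes: {int(self.success.sum())}/{len(self.seeds)}"
                 f"  ({100 * self.success_rate:.0f}%)"]
        return "\n".join(lines)


class RatchetSimulation:
    """Overdamped Langevin dynamics with a ratchet-and-pawl bias on
    ξ = eRMSD(current, target)."""

    def __init__(self, model: CGModel, n_steps: int = 24000,
                 dt_mobility: float = 0.02, temperature: float = T_DEFAULT,
                 k_bias: float = 200.0, threshold: float = 0.7,
                 frame_stride: int = 200):
        self.model = model
        self.n_steps = n_steps
        self.dt_mobility = dt_mobility     # mobility·dt, Å²·mol/kcal
        self.temperature = temperature
        self.k_bias = k_bias
        self.threshold = threshold
        self.frame_stride = frame_stride

    def run(self, seeds) -> TransitionRun:
        model = self.model
        seeds = list(seeds)
        B = len(seeds)
        rngs = [np.random.default_rng(int(s)) for s in seeds]
        x = np.repeat(model.coords_start[None], B, axis=0)
        target_rings = model.coords_target[model.ring_index]
        g_ref = _gvec_batch(target_rings[None])[0]
        kT = kt(self.temperature)
        h = self.dt_mobility
        noise_scale = np.sqrt(2.0 * kT * h)
        rsh = (B, len(model.ring_index), 3, 3)
        xi, grad = _ermsd_grad_batch(
            x[:, model.ring_index.ravel()].reshape(rsh), g_ref)
        xi_best = xi.copy()
        series = np.empty((B, self.n_steps + 1))
        series[:, 0] = xi
        n_saved = self.n_steps // self.frame_stride + 1
        frames = np.empty((B, n_saved, model.n_beads, 3))
        frames[:, 0] = x
        save_k = 1
        ring_flat = model.ring_index.ravel()
        for step in range(1, self.n_steps + 1):
            _, f = model.energy_forces(x)
            if self.k_bias > 0:
                # one-sided pawl: force −k(ξ−ξ_best)·∇ξ when ξ > ξ_best,
                # spread over each base's three ring beads
                push = -self.k_bias * np.maximum(xi - xi_best, 0.0)
                bead_bias = push[:, None, None, None] * grad    # (B, N, 3, 3)
                np.add.at(f, (slice(None), ring_flat),
                          bead_bias.reshape(len(seeds), -1, 3))
            noise = np.stack([r.standard_normal(x.shape[1:]) for r in rngs])
            x = x + h * f + noise_scale * noise
            if np.max(np.abs(x)) > 1e3:
                raise InstabilityError(f"coordinates diverged at step {step}")
            xi, grad = _ermsd_grad_batch(
                x[:, ring_flat].reshape(rsh), g_ref)
            xi_best = np.minimum(xi_best, xi)
            series[:, step] = xi
            if step % self.frame_stride == 0:
                frames[:, save_k] = x
                save_k += 1
        success = series.min(axis=1) < self.threshold
        return TransitionRun(scenario=model.protonation, seeds=seeds,
                             n_steps=self.n_steps, temperature=self.temperature,
                             k_bias=self.k_bias, threshold=self.threshold,
                             xi_series=series, success=success,
                             frames=frames[:, :save_k],
                             frame_stride=self.frame_stride, model=model)


def run_rmd(model: CGModel, seeds=range(20), n_steps: int = 24000,
            k_bias: float = 200.0, threshold: float = 0.7,
            temperature: float = T_DEFAULT, **kwargs) -> TransitionRun:
    """Functional wrapper around :class:`RatchetSimulation`."""
    sim = RatchetSimulation(model, n_steps=n_steps, k_bias=k_bias,
                            threshold=threshold, temperature=temperature,
                            **kwargs)
    return sim.run(seeds)


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------

def _point_line_distance(points, a, b):
    """Distances from points (.., 3) to the line through a, b."""
    u = b - a
    u = u / np.linalg.norm(u, axis=-1, keepdims=True)
    w = points - a[..., None, :]
    proj = (w * u[..., None, :]).sum(axis=-1, keepdims=True) * u[..., None, :]
    return np.linalg.norm(w - proj, axis=-1)


def transition_summary(run: TransitionRun, stack_radius: float = 4.0,
                       bins: int = 12):
    """Per-frame observables of a run.

    Returns a dict with per-frame arrays ``gplane_distance`` (distance
    between the mean planes of the two tetrad guanine groups, Å) and
    ``n_stack`` (how many of the switching cytosines C1/C6/C14/C19 have
    their ring centroid within ``stack_radius`` of the C:C+ stack axis),
    plus a 2-D occupancy histogram over the two.
    """
    model = run.model
    res_pos = {idx: k for k, idx in enumerate(model.residue_indices)}
    g_idx = [res_pos[i] for i in (3, 16) if i in res_pos]
    g2_idx = [res_pos[i] for i in (8, 21) if i in res_pos]
    mon = [res_pos[i] for i in SWITCHING_CYTOSINES if i in res_pos]
    ax_a = [res_pos[i] for i in (2, 20) if i in res_pos]
    ax_b = [res_pos[i] for i in (7, 15) if i in res_pos]
    frames = run.frames.reshape(-1, model.n_beads, 3)    # (F, n, 3)
    ring = frames[:, model.ring_index.ravel()].reshape(
        len(frames), len(model.ring_index), 3, 3)
    centroids = ring.mean(axis=2)                        # (F, n_res, 3)
    gplane = np.linalg.norm(centroids[:, g_idx].mean(axis=1)
                            - centroids[:, g2_idx].mean(axis=1), axis=-1)
    a = centroids[:, ax_a].mean(axis=1)
    b = centroids[:, ax_b].mean(axis=1)
    dists = _point_line_distance(centroids[:, mon], a, b)
    n_stack = (dists < stack_radius).sum(axis=-1)
    hist, xe, ye = np.histogram2d(gplane, n_stack,
                                  bins=[bins, np.arange(-0.5, len(mon) + 1)])
    return {"gplane_distance": gplane, "n_stack": n_stack,
            "histogram": hist, "gplane_edges": xe, "n_stack_edges": ye,
            "n_frames": len(frames)}
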