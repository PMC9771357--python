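"""Cerebellar network construction and 1-ms-step dynamics.

The circuit is laid out on a normalized 2-D sheet (x = transverse axis,
along which parallel fibers run; y = sagittal axis).  Wiring is random
within per-projection *eligibility spans* -- rectangular regions of the
sheet within which a source may contact a target -- at fixed convergence
counts, so the known divergence/convergence ratios hold at any scale.

Dynamics: each neuron is a leaky conductance-based point neuron with one
excitatory and one inhibitory conductance accumulator and an adaptive
spike threshold (threshold jumps at each spike and relaxes exponentially
to baseline).  Mossy fibers and climbing fibers are source-only rows
driven externally by the conditioning protocol.  All synapses deliver
with a one-step (1 ms) delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .config import (ALL_POPULATIONS, CONVERGENCE, ConfigurationError,
                     NeuronParams, SimConfig)


class NumericalFailure(RuntimeError):
    """Non-finite membrane potential or conductance during integration."""


# ---------------------------------------------------------------------------
# wiring
# ---------------------------------------------------------------------------

@dataclass
class Projection:
    """A wired projection stored target-major (CSR-like ragged arrays)."""

    source: str
    target: str
    channel: str                      # "exc" or "inh"
    indptr: np.ndarray                # len n_target + 1
    sources: np.ndarray               # flat source indices
    weights: np.ndarray               # flat per-edge weights
    span_half_x: float = 0.5          # eligibility half-width (transverse)
    span_half_y: float = 0.5          # eligibility half-height (sagittal)

    @property
    def n_edges(self) -> int:
        return len(self.sources)

    def sources_of(self, t: int) -> np.ndarray:
        return self.sources[self.indptr[t]:self.indptr[t + 1]]

    def to_csr(self, n_target: int, n_source: int) -> sp.csr_matrix:
        """Target x source matrix accumulating duplicate edges."""
        m = sp.csr_matrix(
            (self.weights, self.sources, self.indptr), shape=(n_target, n_source)
        )
        m.sum_duplicates()
        return m


#: nominal eligibility spans (half-width x, half-height y) in sheet units
SPANS = {
    ("mf", "grc"): (0.15, 0.15),
    ("goc", "grc"): (0.15, 0.15),
    ("mf", "goc"): (0.20, 0.20),
    ("grc", "goc"): (0.50, 0.05),   # parallel-fiber beam: narrow transverse rectangle
    ("grc", "pc"): (0.50, 0.10),
    ("grc", "bc"): (0.50, 0.05),
    ("grc", "sc"): (0.50, 0.05),
    ("bc", "pc"): (0.50, 0.15),
    ("sc", "pc"): (0.50, 0.15),
    ("pc", "pcmli"): (0.50, 0.20),
    ("mf", "dcn"): (0.50, 0.50),    # nuclear projections are non-topographic
    ("pc", "dcn"): (0.50, 0.50),
}


def _sample_in_span(rng, src_x, src_y, cx, cy, hx, hy, k):
    """Pick ``k`` distinct sources inside the rectangle centered at (cx, cy).

    The span is doubled (up to the full sheet) if it holds fewer than ``k``
    candidates; returns (indices, half_x, half_y actually used).
    """
    while True:
        inside = np.flatnonzero(
            (np.abs(src_x - cx) <= hx) & (np.abs(src_y - cy) <= hy)
        )
        if len(inside) >= k or (hx >= 1.0 and hy >= 1.0):
            break
        hx, hy = min(1.0, 2 * hx), min(1.0, 2 * hy)
    if len(inside) < k:
        raise ConfigurationError(
            f"cannot draw {k} sources from a population of {len(src_x)}"
        )
    return rng.choice(inside, size=k, replace=False), hx, hy


@dataclass
class Network:
    """Wired network: config, placements, projections, and run state."""

    config: SimConfig
    positions: dict                      # pop -> (x, y) arrays
    projections: dict                    # (src, tgt[,tag]) -> Projection
    pcmli_indices: np.ndarray            # BC indices designated PC-MLI
    cf_of_pc: np.ndarray                 # climbing fiber feeding each PC
    pf_target_pc: np.ndarray             # PC contacted by each granule cell
    # compiled state (filled by _compile)
    _sim: "_CompiledSim" = field(default=None, repr=False)

    @property
    def n_total(self) -> int:
        return sum(self.config.counts.values())

    def offsets(self) -> dict[str, int]:
        off, acc = {}, 0
        for pop in ALL_POPULATIONS:
            off[pop] = acc
            acc += self.config.counts[pop]
        return off

    # plastic weight views -------------------------------------------------

    @property
    def pf_weights(self) -> np.ndarray:
        """Granule->PC parallel-fiber weights (one synapse per granule cell)."""
        return self._sim.pf_weights

    @pf_weights.setter
    def pf_weights(self, w: np.ndarray) -> None:
        self._sim.set_pf_weights(np.asarray(w, dtype=float))

    @property
    def mf_dcn_weights(self) -> np.ndarray:
        return self._sim.mf_dcn_weights

    @mf_dcn_weights.setter
    def mf_dcn_weights(self, w: np.ndarray) -> None:
        self._sim.set_mf_dcn_weights(np.asarray(w, dtype=float))

    def reset_state(self) -> None:
        self._sim.reset()

    def write_edge_list(self, path) -> None:
        """Dump adjacency as CSV: source_pop,source_idx,target_pop,target_idx,weight."""
        import csv
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["source_pop", "source_idx", "target_pop", "target_idx", "weight"])
            for key, proj in self.projections.items():
                tgt_pop = "bc" if proj.target == "pcmli" else proj.target
                for t in range(len(proj.indptr) - 1):
                    for j in range(proj.indptr[t], proj.indptr[t + 1]):
                        w.writerow([proj.source, proj.sources[j], tgt_pop, t,
                                    f"{proj.weights[j]:.6g}"])


def build_network(config: SimConfig) -> Network:
    """Wire the full circuit; deterministic for a given ``config.seed``.

    The PC->PC-MLI feedback projection is always *constructed* (so that a
    feedback-off build is edge-for-edge identical elsewhere at the same
    seed) but is compiled with zero edges when ``feedback_enabled`` is
    False.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    c = config.counts

    # --- placements on the unit sheet ------------------------------------
    positions = {}
    for pop in ("mf", "grc", "goc", "bc", "sc"):
        n = c[pop]
        positions[pop] = (rng.uniform(0, 1, n), rng.uniform(0, 1, n))
    # PCs form an evenly spaced sagittal row (monolayer)
    pc_y = (np.arange(c["pc"]) + 0.5) / c["pc"]
    positions["pc"] = (np.full(c["pc"], 0.5), pc_y)
    positions["dcn"] = (np.full(c["dcn"], 0.5), (np.arange(c["dcn"]) + 0.5) / c["dcn"])
    positions["cf"] = (np.full(c["cf"], 0.5), (np.arange(c["cf"]) + 0.5) / c["cf"])

    pcmli = np.sort(rng.choice(c["bc"], size=config.n_pcmli, replace=False))

    w = config.weights
    projections: dict = {}

    def wire(src, tgt, k, weight, channel, tgt_x, tgt_y, span_key=None):
        sx, sy = positions[src]
        hx0, hy0 = SPANS[span_key or (src, tgt)]
        indptr = np.zeros(len(tgt_x) + 1, dtype=np.int64)
        chosen = []
        hx_max = hy_max = 0.0
        for t in range(len(tgt_x)):
            idx, hx, hy = _sample_in_span(rng, sx, sy, tgt_x[t], tgt_y[t], hx0, hy0, k)
            hx_max, hy_max = max(hx_max, hx), max(hy_max, hy)
            chosen.append(np.sort(idx))
            indptr[t + 1] = indptr[t] + k
        sources = np.concatenate(chosen) if chosen else np.empty(0, dtype=np.int64)
        return Projection(src, tgt, channel, indptr, sources,
                          np.full(len(sources), float(weight)),
                          hx_max, hy_max)

    gx, gy = positions["grc"]
    projections[("mf", "grc")] = wire(
        "mf", "grc", min(CONVERGENCE[("mf", "grc")], c["mf"]),
        w[("mf", "grc")], "exc", gx, gy)
    projections[("goc", "grc")] = wire(
        "goc", "grc", min(CONVERGENCE[("goc", "grc")], c["goc"]),
        w[("goc", "grc")], "inh", gx, gy)
    ox, oy = positions["goc"]
    projections[("mf", "goc")] = wire(
        "mf", "goc", min(CONVERGENCE[("mf", "goc")], c["mf"]),
        w[("mf", "goc")], "exc", ox, oy)
    projections[("grc", "goc")] = wire(
        "grc", "goc", min(CONVERGENCE[("grc", "goc")], c["grc"]),
        w[("grc", "goc")], "exc", ox, oy)

    # parallel fibers: every granule cell contacts exactly one PC, drawn
    # among PCs whose (transversely elongated) span covers the granule cell
    hy_pc = SPANS[("grc", "pc")][1]
    pf_target = np.empty(c["grc"], dtype=np.int64)
    for g in range(c["grc"]):
        eligible = np.flatnonzero(np.abs(pc_y - gy[g]) <= hy_pc)
        if len(eligible) == 0:
            eligible = np.array([np.argmin(np.abs(pc_y - gy[g]))])
        pf_target[g] = rng.choice(eligible)
    order = np.argsort(pf_target, kind="stable")
    indptr = np.zeros(c["pc"] + 1, dtype=np.int64)
    np.add.at(indptr, pf_target + 1, 1)
    indptr = np.cumsum(indptr)
    projections[("grc", "pc")] = Projection(
        "grc", "pc", "exc", indptr, order.copy(),
        np.full(c["grc"], float(w[("grc", "pc")])), 0.5, hy_pc)

    for mli in ("bc", "sc"):
        mx, my = positions[mli]
        projections[("grc", mli)] = wire(
            "grc", mli, min(CONVERGENCE[("grc", mli)], c["grc"]),
            w[("grc", mli)], "exc", mx, my)

    px, py = positions["pc"]
    projections[("bc", "pc")] = wire(
        "bc", "pc", min(CONVERGENCE[("bc", "pc")], c["bc"]), w[("bc", "pc")],
        "inh", px, py)
    projections[("sc", "pc")] = wire(
        "sc", "pc", min(CONVERGENCE[("sc", "pc")], c["sc"]), w[("sc", "pc")],
        "inh", px, py)

    # PC -> PC-MLI feedback, excluding reciprocal pairs: a PC never
    # contacts a PC-MLI that already inhibits it
    bcpc = projections[("bc", "pc")]
    inhibits = {(int(b), p) for p in range(c["pc"]) for b in bcpc.sources_of(p)}
    bx, by = positions["bc"]
    k_fb = min(CONVERGENCE[("pc", "pcmli")], c["pc"])
    chosen, indptr = [], np.zeros(config.n_pcmli + 1, dtype=np.int64)
    hy_fb = SPANS[("pc", "pcmli")][1]
    for j, b in enumerate(pcmli):
        hy = hy_fb
        while True:
            cand = np.flatnonzero(np.abs(pc_y - by[b]) <= hy)
            cand = cand[[(int(b), int(p)) not in inhibits for p in cand]]
            if len(cand) >= k_fb or hy >= 1.0:
                break
            hy = min(1.0, 2 * hy)
        take = rng.choice(cand, size=min(k_fb, len(cand)), replace=False)
        chosen.append(np.sort(take))
        indptr[j + 1] = indptr[j] + len(take)
    fb_sources = (np.concatenate(chosen) if chosen else np.empty(0, dtype=np.int64))
    projections[("pc", "pcmli")] = Projection(
        "pc", "pcmli", "inh", indptr, fb_sources,
        np.full(len(fb_sources), float(w[("pc", "pcmli")])), 0.5, 1.0)

    dx, dy = positions["dcn"]
    projections[("mf", "dcn")] = wire(
        "mf", "dcn", min(CONVERGENCE[("mf", "dcn")], c["mf"]), w[("mf", "dcn")],
        "exc", dx, dy)
    projections[("pc", "dcn")] = wire(
        "pc", "dcn", min(CONVERGENCE[("pc", "dcn")], c["pc"]), w[("pc", "dcn")],
        "inh", dx, dy)

    # climbing fibers partition the PC row (one CF per sagittal zone)
    cf_of_pc = (np.arange(c["pc"]) * c["cf"]) // c["pc"]
    indptr = np.arange(c["pc"] + 1, dtype=np.int64)
    projections[("cf", "pc")] = Projection(
        "cf", "pc", "exc", indptr, cf_of_pc.copy(),
        np.full(c["pc"], float(w[("cf", "pc")])), 0.5, 1.0)

    net = Network(config, positions, projections, pcmli, cf_of_pc, pf_target)
    net._sim = _CompiledSim(net)
    return net


# ---------------------------------------------------------------------------
# compiled dynamics
# ---------------------------------------------------------------------------

class _CompiledSim:
    """Stacked-array simulator: one global neuron index space, one CSR
    matrix per channel, so a 1-ms step costs two sparse matvecs plus a
    handful of vectorized elementwise updates."""

    def __init__(self, net: Network):
        cfg = net.config
        counts = cfg.counts
        self.offsets = net.offsets()
        self.n = net.n_total
        n = self.n

        def pervec(attr, default):
            v = np.full(n, default, dtype=float)
            for pop in ("grc", "goc", "pc", "bc", "sc", "dcn"):
                p: NeuronParams = cfg.neuron_params[pop]
                o = self.offsets[pop]
                v[o:o + counts[pop]] = getattr(p, attr)
            return v

        self.gl = pervec("g_leak", 0.0)
        self.el = pervec("e_leak", -70.0)
        self.ee = pervec("e_exc", 0.0)
        self.ei = pervec("e_inh", -80.0)
        self.bias = pervec("bias", 0.0)
        self.vreset = pervec("v_reset", -70.0)
        self.theta0 = pervec("theta0", 1e30)     # MF/CF rows never threshold
        self.dtheta = pervec("dtheta", 0.0)
        self.dec_th = np.exp(-cfg.dt / pervec("tau_theta", 1.0))
        self.dec_e = np.exp(-cfg.dt / pervec("tau_exc", 1.0))
        self.dec_i = np.exp(-cfg.dt / pervec("tau_inh", 1.0))
        # designated PC-MLIs get a compensatory bias for the tonic
        # Purkinje-collateral inhibition they receive; without the
        # feedback projection there is nothing to compensate
        if cfg.feedback_enabled:
            self.bias[self.offsets["bc"] + net.pcmli_indices] += cfg.pcmli_bias_extra
        # source-only rows keep V fixed and theta at +inf
        for pop in ("mf", "cf"):
            o, m = self.offsets[pop], counts[pop]
            self.gl[o:o + m] = 0.0
            self.theta0[o:o + m] = 1e30

        # global CSR per channel
        rows = {"exc": [], "inh": []}
        cols = {"exc": [], "inh": []}
        data = {"exc": [], "inh": []}
        edge_tag = {"exc": [], "inh": []}   # (projection key, flat edge idx)
        for key, proj in net.projections.items():
            if key == ("pc", "pcmli") and not cfg.feedback_enabled:
                continue
            tgt_pop = "bc" if proj.target == "pcmli" else proj.target
            t_off = self.offsets[tgt_pop]
            s_off = self.offsets[proj.source]
            n_t = len(proj.indptr) - 1
            tgt_idx = np.repeat(np.arange(n_t), np.diff(proj.indptr))
            if proj.target == "pcmli":
                tgt_idx = net.pcmli_indices[tgt_idx]
            rows[proj.channel].append(tgt_idx + t_off)
            cols[proj.channel].append(proj.sources + s_off)
            data[proj.channel].append(proj.weights.astype(float))
            edge_tag[proj.channel].extend(
                (key, j) for j in range(proj.n_edges))

        self.W = {}
        self._plastic_pos = {}
        for ch in ("exc", "inh"):
            if rows[ch]:
                r = np.concatenate(rows[ch])
                c_ = np.concatenate(cols[ch])
                d = np.concatenate(data[ch])
            else:
                r = c_ = np.empty(0, dtype=np.int64)
                d = np.empty(0)
            coo = sp.coo_matrix((d, (r, c_)), shape=(n, n))
            # build CSR without summing duplicates so each wired edge keeps
            # its own data slot (required for plastic weight updates)
            order = np.lexsort((c_, r))
            indptr = np.zeros(n + 1, dtype=np.int64)
            np.add.at(indptr, r + 1, 1)
            indptr = np.cumsum(indptr)
            csr = sp.csr_matrix((d[order], c_[order], indptr), shape=(n, n))
            self.W[ch] = csr
            # map (projection key, edge idx) -> position in csr.data
            pos_of = np.empty(len(order), dtype=np.int64)
            pos_of[order] = np.arange(len(order))
            tags = edge_tag[ch]
            by_proj: dict = {}
            for flat, (key, j) in enumerate(tags):
                by_proj.setdefault(key, []).append((j, pos_of[flat]))
            for key, pairs in by_proj.items():
                pairs.sort()
                self._plastic_pos[key] = (ch, np.array([p for _, p in pairs]))
            del coo

        # parallel-fiber synapses indexed by granule cell
        self._pf_edge_order = None
        if ("grc", "pc") in self._plastic_pos:
            ch, pos = self._plastic_pos[("grc", "pc")]
            # edge j of the (grc, pc) projection corresponds to granule
            # cell net.pf-sorted order; recover granule identity per edge
            proj = net.projections[("grc", "pc")]
            self._pf_grc_of_edge = proj.sources          # granule cell per edge
            self._pf_ch, self._pf_pos = ch, pos
        mfd = net.projections[("mf", "dcn")]
        self._mfdcn_ch, self._mfdcn_pos = self._plastic_pos[("mf", "dcn")]
        self._mfdcn_src = mfd.sources
        self.net = net
        self.reset()

    # -- plastic weight access (granule-cell order) ------------------------

    @property
    def pf_weights(self) -> np.ndarray:
        w_edge = self.W[self._pf_ch].data[self._pf_pos]
        w = np.empty(len(self._pf_grc_of_edge))
        w[self._pf_grc_of_edge] = w_edge
        return w

    def set_pf_weights(self, w_by_grc: np.ndarray) -> None:
        self.W[self._pf_ch].data[self._pf_pos] = w_by_grc[self._pf_grc_of_edge]

    @property
    def mf_dcn_weights(self) -> np.ndarray:
        return self.W[self._mfdcn_ch].data[self._mfdcn_pos].copy()

    def set_mf_dcn_weights(self, w: np.ndarray) -> None:
        self.W[self._mfdcn_ch].data[self._mfdcn_pos] = w

    def reset(self) -> None:
        self.V = self.el.copy()
        self.theta = self.theta0.copy()
        self.g_exc = np.zeros(self.n)
        self.g_inh = np.zeros(self.n)
        self.spikes = np.zeros(self.n)          # spikes emitted last step

    def step(self, external: Optional[np.ndarray] = None) -> np.ndarray:
        """Advance one 1-ms step; returns the boolean spike vector."""
        s = self.spikes
        self.g_exc *= self.dec_e
        self.g_exc += self.W["exc"] @ s
        self.g_inh *= self.dec_i
        self.g_inh += self.W["inh"] @ s
        # exponential-Euler membrane update: relax toward the effective
        # reversal at the total conductance rate (stable for any g_tot)
        V = self.V
        g_tot = self.gl + self.g_exc + self.g_inh
        num = (self.gl * self.el + self.g_exc * self.ee
               + self.g_inh * self.ei + self.bias)
        g_safe = np.maximum(g_tot, 1e-12)
        e_eff = num / g_safe
        V[:] = np.where(g_tot > 0, e_eff + (V - e_eff) * np.exp(-g_tot), V)
        spiked = V >= self.theta
        V[spiked] = self.vreset[spiked]
        self.theta = self.theta0 + (self.theta - self.theta0) * self.dec_th
        self.theta[spiked] += self.dtheta[spiked]
        out = spiked.astype(float)
        if external is not None:
            out = np.maximum(out, external)
        self.spikes = out
        return spiked | (out > 0)

    def check_finite(self) -> None:
        bad = ~np.isfinite(self.V)
        if bad.any():
            raise NumericalFailure(
                f"non-finite membrane potential at neuron {int(np.flatnonzero(bad)[0])}")


# ---------------------------------------------------------------------------
# public per-step operations
# ---------------------------------------------------------------------------

def advance_timestep(network: Network, external_drive: Optional[dict] = None):
    """Advance the network one 1-ms step.

    ``external_drive`` maps population name ("mf", "cf") to a boolean/0-1
    spike array for this step.  Returns a dict population -> boolean spike
    array.  Raises :class:`NumericalFailure` if state becomes non-finite.
    """
    sim = network._sim
    ext = None
    if external_drive:
        ext = np.zeros(sim.n)
        for pop, spikes in external_drive.items():
            spikes = np.asarray(spikes)
            o = sim.offsets[pop]
            if len(spikes) != network.config.counts[pop]:
                raise ValueError(f"drive length mismatch for population {pop!r}")
            ext[o:o + len(spikes)] = spikes.astype(float)
    spiked = sim.step(ext)
    sim.check_finite()
    out = {}
    for pop in ALL_POPULATIONS:
        o = sim.offsets[pop]
        out[pop] = spiked[o:o + network.config.counts[pop]]
    return out


def update_threshold(theta: np.ndarray, params: NeuronParams,
                     spiked: np.ndarray, dt: float = 1.0) -> np.ndarray:
    """Adaptive-threshold update: exponential relaxation to ``theta0``
    plus a fixed increment for every neuron that spiked this step."""
    if params.tau_theta <= 0:
        raise ConfigurationError("tau_theta must be > 0")
    theta = params.theta0 + (theta - params.theta0) * np.exp(-dt / params.tau_theta)
    return theta + params.dtheta * np.asarray(spiked, dtype=float)


def update_conductances(g: np.ndarray, tau: float, increment: float,
                        spike_counts: np.ndarray, dt: float = 1.0) -> np.ndarray:
    """Exponential conductance decay plus per-spike increments."""
    if tau <= 0:
        raise ConfigurationError("synaptic tau must be > 0")
    counts = np.asarray(spike_counts)
    if (counts < 0).any():
        raise ValueError("negative spike count")
    return g * np.exp(-dt / tau) + increment * counts
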