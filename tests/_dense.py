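"""Naive dense-matrix reference simulator, used as an independent oracle.

Deliberately simple: plain Python loops over dense N x N matrices, one
scalar arithmetic expression per update, no vectorization and no sharing
of code with the package engine.  Arithmetic expressions are written in
the same left-to-right order as the model's update equations so
that float-mode results are comparable bit for bit.

Only unique (pre, post) synapse pairs are supported (dense matrices).
"""

from typing import Dict, List, Sequence, Tuple


class DenseReference:
    def __init__(self, net):
        self.n = net.n_neurons
        self.params = [p for p, _ in net.neurons]
        self.v = [s.v for _, s in net.neurons]
        self.u = [s.u for _, s in net.neurons]
        self.I_bias = [s.I_bias for _, s in net.neurons]
        self.I_exc = [s.I_exc for _, s in net.neurons]
        self.I_inh = [s.I_inh for _, s in net.neurons]
        self.its = net.inv_tau_syn
        n = self.n
        self.conn = [[False] * n for _ in range(n)]
        self.W = [[0.0] * n for _ in range(n)]
        self.P = [[0.0] * n for _ in range(n)]
        self.itr = [[0.0] * n for _ in range(n)]
        self.delta = [[0.0] * n for _ in range(n)]
        for pre, post, sp, ss in net.connectivity.edges():
            if self.conn[pre][post]:
                raise ValueError("dense reference needs unique (pre, post) pairs")
            self.conn[pre][post] = True
            self.W[pre][post] = sp.W_syn
            self.P[pre][post] = sp.P
            self.itr[pre][post] = sp.inv_tau_reg
            self.delta[pre][post] = ss.delta

    def step(self, externals: Sequence = ()) -> List[int]:
        n = self.n
        # EXT
        for ev in externals:
            if ev.weight > 0:
                self.I_exc[ev.target] = self.I_exc[ev.target] + ev.weight
            elif ev.weight < 0:
                self.I_inh[ev.target] = self.I_inh[ev.target] + ev.weight
        # NEUR: membrane from pre-decay currents; then current decay
        spiked = [False] * n
        for i in range(n):
            p = self.params[i]
            v, u = self.v[i], self.u[i]
            v_new = (v * v / 32 + 5.0 * v + 109.375 - u
                     + self.I_bias[i] + self.I_exc[i] + self.I_inh[i])
            u_new = u + p.a * (p.b * v - u)
            if v_new >= p.v_thresh:
                spiked[i] = True
                self.v[i] = p.c
                self.u[i] = u_new + p.d
            else:
                self.v[i] = v_new
                self.u[i] = u_new
        for i in range(n):
            self.I_exc[i] = self.I_exc[i] * (1.0 - self.its)
            self.I_inh[i] = self.I_inh[i] * (1.0 - self.its)
        # depression update (exclusive: increment on spike, else recovery)
        # and SYN injection for spiking presynaptic neurons
        inject: List[Tuple[int, float]] = []
        for pre in range(n):
            for post in range(n):
                if not self.conn[pre][post]:
                    continue
                if spiked[pre]:
                    w_s = self.W[pre][post] * (1.0 - self.delta[pre][post])
                    inject.append((post, w_s))
                    self.delta[pre][post] = (
                        self.delta[pre][post]
                        + self.P[pre][post] * (1.0 - self.delta[pre][post])
                    )
                else:
                    self.delta[pre][post] = (
                        self.delta[pre][post] * (1.0 - self.itr[pre][post])
                    )
        for post, w_s in inject:
            if w_s > 0:
                self.I_exc[post] = self.I_exc[post] + w_s
            elif w_s < 0:
                self.I_inh[post] = self.I_inh[post] + w_s
        return [i for i in range(n) if spiked[i]]

    def run(self, steps: int, externals: Sequence = ()) -> List[Tuple[int, int]]:
        by_step: Dict[int, list] = {}
        for ev in externals:
            by_step.setdefault(ev.t, []).append(ev)
        events = []
        for t in range(steps):
            for i in self.step(by_step.get(t, ())):
                events.append((t, i))
        return events
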