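"""Compilation and simulation of the receptor signaling ODE model.

The state inventory is the smallest one that supports every arrow of the
network: per receptor a free surface monomer and (per cognate ligand) a
ligand-bound monomer; per dimer a phosphorylated surface pool and an
internalized pool; downstream the active fractions of MEK, ERK, AKT, S6K1
and S6 with conserved totals.  Dimer formation and trans-phosphorylation are
collapsed into one step (the non-signaling ErbB3 homodimer forms but stays
unphosphorylated and carries zero pathway weight).  Ligand is a constant
bath input, not a state.

The ligand-free basal state is solved analytically for the receptor layer
(per-receptor synthesis rates are chosen so that the measured surface
expression *is* the basal free-monomer level) and by damped 1-d root
bracketing for the two feedback-coupled cascade fixed points, with a
long-horizon pre-equilibration fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import odeint, solve_ivp
from scipy.optimize import brentq

try:  # optional JIT of the right-hand side; the numpy path is equivalent
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco


@_njit(cache=False)
def _rhs_kernel(t, x, u, synth, nr, nl, nd, da, db, lig_rec,
                ka, kd, kint, krec, kdegd, w_mapk, w_pi3k,
                kdeg_rec, kon, koff, M, dsp, internal, i_down):
    dx = np.zeros_like(x)
    Bc = np.zeros((nr, nd))
    for j in range(nl):
        r = lig_rec[j]
        for d in range(nd):
            Bc[r, d] += M[j, d] * x[nr + j]
    SM = 0.0
    SP = 0.0
    for d in range(nd):
        a = da[d]
        b = db[d]
        Ca = x[a] + Bc[a, d]
        Cb = x[b] + Bc[b, d]
        F = ka[d] * Ca * Cb
        ids = nr + nl + 2 * d
        Ds = x[ids]
        Di = x[ids + 1]
        dx[ids] += F - (kd[d] + kint[d]) * Ds
        dx[ids + 1] += kint[d] * Ds - (krec[d] + kdegd[d]) * Di
        rel = kd[d] * Ds + krec[d] * Di
        dx[a] += rel - ka[d] * x[a] * Cb
        dx[b] += rel - ka[d] * x[b] * Ca
        pool = Ds + Di if internal else Ds
        SM += w_mapk[d] * pool
        SP += w_pi3k[d] * pool
    for r in range(nr):
        dx[r] += synth[r] - kdeg_rec[r] * x[r]
    for j in range(nl):
        r = lig_rec[j]
        B = x[nr + j]
        bind = kon[j] * u[j] * x[r]
        unbind = koff[j] * B
        cons = 0.0
        for d in range(nd):
            if da[d] == r:
                cons += ka[d] * M[j, d] * (x[db[d]] + Bc[db[d], d])
            if db[d] == r:
                cons += ka[d] * M[j, d] * (x[da[d]] + Bc[da[d], d])
        dx[nr + j] += bind - unbind - cons * B
        dx[r] += unbind - bind
    pMEK = x[i_down]
    pERK = x[i_down + 1]
    pAKT = x[i_down + 2]
    pS6K1 = x[i_down + 3]
    pS6 = x[i_down + 4]
    uM = SM / dsp[13] / (1.0 + dsp[11] * pERK)
    uP = SP / dsp[13] / (1.0 + dsp[12] * pS6K1)
    dx[i_down] = dsp[0] * uM * (1 - pMEK) - dsp[1] * pMEK
    dx[i_down + 1] = dsp[2] * pMEK * (1 - pERK) - dsp[3] * pERK
    dx[i_down + 2] = dsp[4] * uP * (1 - pAKT) - dsp[5] * pAKT
    dx[i_down + 3] = (dsp[6] * pERK + dsp[7] * pAKT) * (1 - pS6K1) - dsp[8] * pS6K1
    dx[i_down + 4] = dsp[9] * pS6K1 * (1 - pS6) - dsp[10] * pS6
    return dx

from .network import CellLineContext, ModelSpec, StimulusCondition, dimer_name
from .params import ConfigurationError, KineticParameterSet

DOWNSTREAM = ("pMEK", "pERK", "pAKT", "pS6K1", "pS6")

#: residual tolerance of the basal steady state, in normalized units
#: |f_i| / (1 + |x_i|)
TOL_SS = 1e-8


class NonConvergenceError(RuntimeError):
    """Basal steady-state solving failed even after pre-equilibration."""


class NumericalError(RuntimeError):
    """The ODE integrator failed mid-trajectory."""


@dataclass
class BasalState:
    """Ligand-free steady state plus the per-receptor synthesis rates
    solved from the steady-state balance."""

    x0: np.ndarray
    synthesis: np.ndarray
    residual: float


@dataclass
class Trajectory:
    """Time-resolved states and derived phospho-observables."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_states)
    model: "CompiledModel"
    cell_line: str = ""
    condition: str = "basal"

    def state(self, name: str) -> np.ndarray:
        return self.states[:, self.model.state_index[name]]

    def observable(self, name: str) -> np.ndarray:
        return self.model.observable_matrix(name) @ self.states.T

    def observables(self) -> "dict[str, np.ndarray]":
        return {name: self.observable(name) for name in self.model.observable_names}

    def to_tidy(self):
        """Long-format table: cell_line, ligand_condition, time_min, species, value."""
        import pandas as pd

        rows = []
        for name, values in self.observables().items():
            for t, v in zip(self.times, values):
                rows.append((self.cell_line, self.condition, float(t), name, float(v)))
        return pd.DataFrame(
            rows, columns=["cell_line", "ligand_condition", "time_min", "species", "value"]
        )


class CompiledModel:
    """Evaluable right-hand side of the signaling network.

    Built once per (spec, parameter set); shared across cell lines.  Basal
    states are cached per cell line.
    """

    def __init__(self, spec: ModelSpec, params: KineticParameterSet, validate: bool = True):
        if validate:
            spec.validate()
            params.validate(spec)
        self.spec = spec
        self.params = params
        self._compile()
        self._basal_cache: dict = {}

    # ------------------------------------------------------------------
    def _compile(self) -> None:
        spec, params = self.spec, self.params
        self.receptors = spec.receptors
        self.ligand_names = tuple(spec.ligands)
        self.dimer_names = tuple(dimer_name(p) for p in spec.dimers)
        nr, nl, nd = len(self.receptors), len(self.ligand_names), len(spec.dimers)
        self.nr, self.nl, self.nd = nr, nl, nd

        ridx = {r: i for i, r in enumerate(self.receptors)}
        self.da = np.array([ridx[a] for a, _ in spec.dimers], dtype=int)
        self.db = np.array([ridx[b] for _, b in spec.dimers], dtype=int)
        self._ar = np.arange(nd)

        dim = params.dimer
        self.ka = np.array([dim[n]["ka"] for n in self.dimer_names])
        self.kd = np.array([dim[n]["kd"] for n in self.dimer_names])
        self.kint = np.array([dim[n]["kint"] for n in self.dimer_names])
        self.krec = np.array([dim[n]["krec"] for n in self.dimer_names])
        self.kdeg_dimer = np.array([dim[n]["kdeg"] for n in self.dimer_names])
        self.w_mapk = np.array([dim[n]["w_mapk"] for n in self.dimer_names])
        self.w_pi3k = np.array([dim[n]["w_pi3k"] for n in self.dimer_names])

        self.kdeg_rec = np.array([params.receptor[r]["kdeg"] for r in self.receptors])
        self.synth_nominal = np.array([params.receptor[r]["synth"] for r in self.receptors])

        self.lig_rec = np.array([ridx[spec.ligands[l][0]] for l in self.ligand_names], dtype=int)
        self.kon = np.array([params.ligand[l]["kon"] for l in self.ligand_names])
        self.koff = np.array([params.koff(spec, l) for l in self.ligand_names])

        # dimerization competence of a ligand-bound monomer, per (ligand, dimer)
        self.M = np.empty((nl, nd))
        for j, lig in enumerate(self.ligand_names):
            for d, name in enumerate(self.dimer_names):
                self.M[j, d] = params.phi_ligand * params.multiplier(lig, name)
        # a ligand-bound monomer only enters dimers containing its receptor
        self.maskA = (self.da[None, :] == self.lig_rec[:, None]).astype(float)
        self.maskB = (self.db[None, :] == self.lig_rec[:, None]).astype(float)

        # receptor-side incidence matrices: Sa[r, d] = 1 iff receptor r is
        # the a-side of dimer d (homodimers hit both sides -> multiplicity 2)
        self.Sa = np.zeros((nr, nd))
        self.Sb = np.zeros((nr, nd))
        self.Sa[self.da, self._ar] = 1.0
        self.Sb[self.db, self._ar] = 1.0
        self.Arec = self.Sa + self.Sb

        ds = params.downstream
        self._dsp = (
            ds["kact_mek"], ds["kdeact_mek"], ds["kact_erk"], ds["kdeact_erk"],
            ds["kact_akt"], ds["kdeact_akt"], ds["kact_s6k1_erk"], ds["kact_s6k1_akt"],
            ds["kdeact_s6k1"], ds["kact_s6"], ds["kdeact_s6"],
            ds["fb_erk"], ds["fb_s6k1"], ds["signal_scale"],
        )
        self.internal_signaling = params.internal_signaling

        # state layout (continued below); pack for the jitted kernel
        self._dsp_arr = np.array(self._dsp, dtype=float)

        # state layout
        names = list(self.receptors)
        names += [f"{self.receptors[self.lig_rec[j]]}.{l}" for j, l in enumerate(self.ligand_names)]
        for n in self.dimer_names:
            names += [f"{n}.surf", f"{n}.int"]
        names += list(DOWNSTREAM)
        self.state_names = tuple(names)
        self.state_index = {n: i for i, n in enumerate(names)}
        self.n_states = len(names)
        self._i_ds = nr + nl + 2 * self._ar
        self._i_di = self._i_ds + 1
        self._i_down = self.n_states - 5

        self._pack = (
            nr, nl, nd, self.da, self.db, self.lig_rec,
            self.ka, self.kd, self.kint, self.krec, self.kdeg_dimer,
            self.w_mapk, self.w_pi3k, self.kdeg_rec, self.kon, self.koff,
            self.M, self._dsp_arr, self.internal_signaling, self._i_down,
        )

        self._build_observables()

    def _build_observables(self) -> None:
        obs: dict[str, np.ndarray] = {}
        sig = np.array([self.spec.signaling_mask[p] for p in self.spec.dimers])
        for d, name in enumerate(self.dimer_names):
            if sig[d]:
                row = np.zeros(self.n_states)
                row[self._i_ds[d]] = row[self._i_di[d]] = 1.0
                obs[f"p{name}"] = row
        for i, r in enumerate(self.receptors):
            row = np.zeros(self.n_states)
            mult = self.Arec[i] * sig  # phospho-receptor copies per dimer
            row[self._i_ds] += mult
            row[self._i_di] += mult
            obs[f"p{r}"] = row
        for k, n in enumerate(DOWNSTREAM):
            row = np.zeros(self.n_states)
            row[self._i_down + k] = 1.0
            obs[n] = row
        self.observable_names = tuple(obs)
        self._obs = obs

    def observable_matrix(self, name: str) -> np.ndarray:
        try:
            return self._obs[name]
        except KeyError as exc:
            raise KeyError(
                f"unknown observable {name!r}; known: {sorted(self._obs)}"
            ) from exc

    def describe(self) -> dict:
        """State inventory summary (counts and names)."""
        return {
            "n_states": self.n_states,
            "n_receptors": self.nr,
            "n_bound_monomers": self.nl,
            "n_dimers": self.nd,
            "n_downstream": 5,
            "state_names": self.state_names,
        }

    # ------------------------------------------------------------------
    def rhs(self, t: float, x: np.ndarray, u: np.ndarray, synth: np.ndarray) -> np.ndarray:
        if _HAVE_NUMBA:
            return _rhs_kernel(t, x, u, synth, *self._pack)
        return self._rhs_numpy(t, x, u, synth)

    def _rhs_numpy(self, t: float, x: np.ndarray, u: np.ndarray, synth: np.ndarray) -> np.ndarray:
        nr, nl = self.nr, self.nl
        R = x[:nr]
        B = x[nr:nr + nl]
        Ds = x[self._i_ds]
        Di = x[self._i_di]
        pMEK, pERK, pAKT, pS6K1, pS6 = x[self._i_down:self._i_down + 5]

        # dimerization competence per (receptor, dimer)
        Bc = np.zeros((nr, self.nd))
        for j in range(nl):
            Bc[self.lig_rec[j]] += self.M[j] * B[j]
        Ca = R[self.da] + Bc[self.da, self._ar]
        Cb = R[self.db] + Bc[self.db, self._ar]
        F = self.ka * Ca * Cb

        dDs = F - (self.kd + self.kint) * Ds
        dDi = self.kint * Ds - (self.krec + self.kdeg_dimer) * Di
        rel = self.kd * Ds + self.krec * Di

        cons_a = self.ka * R[self.da] * Cb
        cons_b = self.ka * R[self.db] * Ca
        dR = synth - self.kdeg_rec * R - self.Sa @ cons_a - self.Sb @ cons_b + self.Arec @ rel

        dB = np.empty(nl)
        for j in range(nl):
            r = self.lig_rec[j]
            bind = self.kon[j] * u[j] * R[r]
            unbind = self.koff[j] * B[j]
            cons_j = B[j] * float(
                np.dot(self.maskA[j], self.ka * self.M[j] * Cb)
                + np.dot(self.maskB[j], self.ka * self.M[j] * Ca)
            )
            dB[j] = bind - unbind - cons_j
            dR[r] += unbind - bind

        pool = Ds + Di if self.internal_signaling else Ds
        (aM, dM, aE, dE, aA, dA, a1, a2, dK, aS, dS, fbE, fbS, scale) = self._dsp
        uM = (self.w_mapk @ pool) / scale / (1.0 + fbE * pERK)
        uP = (self.w_pi3k @ pool) / scale / (1.0 + fbS * pS6K1)

        dx = np.empty_like(x)
        dx[:nr] = dR
        dx[nr:nr + nl] = dB
        dx[self._i_ds] = dDs
        dx[self._i_di] = dDi
        k = self._i_down
        dx[k] = aM * uM * (1 - pMEK) - dM * pMEK
        dx[k + 1] = aE * pMEK * (1 - pERK) - dE * pERK
        dx[k + 2] = aA * uP * (1 - pAKT) - dA * pAKT
        dx[k + 3] = (a1 * pERK + a2 * pAKT) * (1 - pS6K1) - dK * pS6K1
        dx[k + 4] = aS * pS6K1 * (1 - pS6) - dS * pS6
        return dx

    # ------------------------------------------------------------------
    def _basal_receptor_layer(self, E: np.ndarray):
        """Analytic basal dimers and synthesis rates for fixed free-monomer
        levels E (ligand-free, so competence = free monomer)."""
        Ca, Cb = E[self.da], E[self.db]
        F0 = self.ka * Ca * Cb
        Ds0 = F0 / (self.kd + self.kint)
        Di0 = self.kint * Ds0 / (self.krec + self.kdeg_dimer)
        rel0 = self.kd * Ds0 + self.krec * Di0
        cons = self.Sa @ (self.ka * E[self.da] * Cb) + self.Sb @ (self.ka * E[self.db] * Ca)
        synth = self.kdeg_rec * E + cons - self.Arec @ rel0
        return Ds0, Di0, synth

    def _basal_downstream(self, Ds0: np.ndarray, Di0: np.ndarray) -> np.ndarray:
        (aM, dM, aE, dE, aA, dA, a1, a2, dK, aS, dS, fbE, fbS, scale) = self._dsp
        pool = Ds0 + Di0 if self.internal_signaling else Ds0
        sM = (self.w_mapk @ pool) / scale
        sP = (self.w_pi3k @ pool) / scale

        def erk_map(p):
            uM = sM / (1.0 + fbE * p)
            mek = aM * uM / (aM * uM + dM)
            return aE * mek / (aE * mek + dE)

        pERK = 0.0 if sM == 0 else brentq(lambda p: erk_map(p) - p, 0.0, 1.0, xtol=1e-15)
        uM = sM / (1.0 + fbE * pERK)
        pMEK = aM * uM / (aM * uM + dM)

        def s6k_map(s):
            uP = sP / (1.0 + fbS * s)
            akt = aA * uP / (aA * uP + dA)
            h = a1 * pERK + a2 * akt
            return h / (h + dK)

        if sP == 0 and pERK == 0:
            pS6K1 = 0.0
        else:
            pS6K1 = brentq(lambda s: s6k_map(s) - s, 0.0, 1.0, xtol=1e-15)
        uP = sP / (1.0 + fbS * pS6K1)
        pAKT = aA * uP / (aA * uP + dA)
        pS6 = aS * pS6K1 / (aS * pS6K1 + dS)
        return np.array([pMEK, pERK, pAKT, pS6K1, pS6])

    def steady_state(self, context: CellLineContext, tol: float = TOL_SS) -> BasalState:
        """Ligand-free basal state; free surface monomers equal the measured
        receptor expression (synthesis rates are solved accordingly)."""
        key = (context.name, tuple(sorted(context.receptor_expression.items())))
        if key in self._basal_cache:
            return self._basal_cache[key]
        E = context.vector(self.spec).astype(float)
        Ds0, Di0, synth = self._basal_receptor_layer(E)
        x0 = np.zeros(self.n_states)
        x0[: self.nr] = E
        x0[self._i_ds] = Ds0
        x0[self._i_di] = Di0
        x0[self._i_down:] = self._basal_downstream(Ds0, Di0)

        u0 = np.zeros(self.nl)
        res = self._normalized_residual(x0, u0, synth)
        if res > tol:
            # fallback: long-horizon pre-equilibration then polish
            sol = solve_ivp(
                self.rhs, (0.0, 1e6), x0, args=(u0, synth),
                method="LSODA", rtol=1e-10, atol=1e-12,
            )
            if sol.success:
                x0 = sol.y[:, -1]
                res = self._normalized_residual(x0, u0, synth)
            if res > tol:
                raise NonConvergenceError(
                    f"basal steady state for {context.name!r} did not converge; "
                    f"final normalized residual {res:.3e} > {tol:.1e}"
                )
        basal = BasalState(x0=x0, synthesis=synth, residual=res)
        self._basal_cache[key] = basal
        return basal

    def _normalized_residual(self, x, u, synth) -> float:
        f = self.rhs(0.0, x, u, synth)
        return float(np.max(np.abs(f) / (1.0 + np.abs(x))))

    # ------------------------------------------------------------------
    def _dose_vector(self, doses: dict[str, float]) -> np.ndarray:
        u = np.zeros(self.nl)
        for lig, dose in doses.items():
            if lig not in self.ligand_names:
                raise ConfigurationError(f"unknown ligand {lig!r}; model has {self.ligand_names}")
            u[self.ligand_names.index(lig)] = dose
        return u

    def simulate(
        self,
        context: CellLineContext | None,
        stim: StimulusCondition,
        x0: np.ndarray | None = None,
        synth: np.ndarray | None = None,
        rtol: float = 1e-8,
        atol: float = 1e-10,
    ) -> Trajectory:
        """Integrate from the basal state with ligand doses applied at t=0.

        ``x0``/``synth`` may be supplied directly (e.g. for conservation
        checks on turnover-free models); otherwise they come from
        :meth:`steady_state` of ``context``.
        """
        if x0 is None or synth is None:
            if context is None:
                raise ValueError("either a context or explicit (x0, synth) is required")
            basal = self.steady_state(context)
            x0 = basal.x0 if x0 is None else x0
            synth = basal.synthesis if synth is None else synth
        u = self._dose_vector(stim.doses)
        grid = np.asarray(stim.time_grid, dtype=float)
        import warnings

        with warnings.catch_warnings():
            # failures are detected from the info dict and raised below
            warnings.simplefilter("ignore")
            states, info = odeint(
                self.rhs, x0, grid, args=(u, synth), tfirst=True,
                rtol=rtol, atol=atol, mxstep=5000, full_output=True, printmessg=False,
            )
        if info["message"] != "Integration successful.":
            t_fail = float(info.get("tcur", [0.0])[-1])
            bad = int(np.argmax(np.abs(self.rhs(t_fail, states[-1], u, synth))))
            raise NumericalError(
                f"integration failed at t={t_fail:.3f} min "
                f"(largest residual on state {self.state_names[bad]!r}): {info['message']}"
            )
        return Trajectory(
            times=grid, states=states, model=self,
            cell_line=context.name if context is not None else "",
            condition=stim.label(),
        )

    # ------------------------------------------------------------------
    def zero_turnover(self) -> "CompiledModel":
        """Copy of the model with synthesis, receptor/dimer degradation and
        recycling removed — receptor copy numbers are then exactly conserved.
        Intended for conservation checks; skips the positivity validation."""
        p = self.params.copy()
        for r in p.receptor.values():
            r["kdeg"] = 0.0
            r["synth"] = 0.0
        for d in p.dimer.values():
            d["kdeg"] = 0.0
            d["krec"] = 0.0
        return CompiledModel(self.spec, p, validate=False)

    def receptor_totals(self, traj: Trajectory) -> np.ndarray:
        """Per-receptor total copies (free + bound + dimer-held, surface and
        internal) along a trajectory; shape (n_times, n_receptors)."""
        X = traj.states
        totals = X[:, : self.nr].copy()
        for j in range(self.nl):
            totals[:, self.lig_rec[j]] += X[:, self.nr + j]
        dim_tot = X[:, self._i_ds] + X[:, self._i_di]
        totals += dim_tot @ self.Arec.T
        return totals


# -- module-level operation surface ------------------------------------

def build_model(spec: ModelSpec, params: KineticParameterSet) -> CompiledModel:
    """Validate and compile the network into an evaluable ODE model."""
    return CompiledModel(spec, params)


def steady_state(model: CompiledModel, context: CellLineContext, tol: float = TOL_SS) -> BasalState:
    return model.steady_state(context, tol=tol)


def simulate(model: CompiledModel, context: CellLineContext, stim: StimulusCondition, **kw) -> Trajectory:
    return model.simulate(context, stim, **kw)
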