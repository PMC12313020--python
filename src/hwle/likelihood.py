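"""Panel log-likelihood of the Gompertz multistate model.

The data are interval censored: living states are known only at
interview ages, while death ages are exact.  Each consecutive pair of
records of one person contributes

* living r at x1, living s at x2:  log P_rs(x1, x2)
* living r at x1, death at xd:     log( sum_j P_rj(x1, xd) * q_j,dead(xd) )

and right censoring after the last living observation contributes
nothing.  P is the piecewise-constant-intensity approximation of
:func:`hwle.transitions.transition_probability` (intensities evaluated
at the left endpoint of each grid cell, grid anchored at the centering
age).

The likelihood is evaluated through a flat, precompiled interval table
(:class:`PanelIntervals`) so that repeated evaluations inside the
optimizer touch no pandas machinery.  A numba-compiled kernel is used
when numba is importable; a vectorized numpy implementation provides the
same numbers otherwise (the two are tested against each other and
against an independent ODE solution of the Kolmogorov forward
equations).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._expm import expm_batch
from .states import ALIVE_OBSERVATION, EXACT_DEATH, PanelRecord
from .transitions import (DEAD, GompertzParams, TRANSITIONS,
                          grid_breakpoints, _LP_CLIP)

logger = logging.getLogger(__name__)

_TR_R = np.array([r - 1 for r, s in TRANSITIONS])
_TR_S = np.array([s - 1 for r, s in TRANSITIONS])
_TR_TO_DEAD = np.array([k for k, (r, s) in enumerate(TRANSITIONS) if s == DEAD])


class LikelihoodUnderflowWarning(UserWarning):
    """An observation pair received probability 0 under the current parameters."""


@dataclass
class PanelIntervals:
    """Flattened consecutive-record pairs of a model-ready panel.

    Segment arrays hold the grid partition of every interval
    (left-endpoint age and width); interval arrays hold origin state,
    destination (state or exact death age) and the covariate profile
    index into ``profiles``.
    """

    seg_age: np.ndarray
    seg_dt: np.ndarray
    itv_start: np.ndarray
    itv_nseg: np.ndarray
    itv_r: np.ndarray          # origin state, 0-based living index
    itv_s: np.ndarray          # destination living index (unused for deaths)
    itv_dead: np.ndarray       # bool
    itv_death_age: np.ndarray
    itv_prof: np.ndarray
    profiles: np.ndarray       # (n_profiles, k) covariate rows
    person_of: np.ndarray      # person id per interval (object, diagnostics)
    n_persons: int
    n_records: int
    grid_step: float
    x0: float


def compile_intervals(panel: pd.DataFrame, covariate_columns=(),
                      grid_step: float = 0.5, x0: float = 51.0
                      ) -> PanelIntervals:
    """Precompute the interval/segment tables for likelihood evaluation."""
    cols = list(covariate_columns)
    if cols:
        zmat = panel[cols].to_numpy(float)
        profiles, prof_idx = np.unique(zmat, axis=0, return_inverse=True)
    else:
        profiles = np.zeros((1, 0))
        prof_idx = np.zeros(len(panel), int)

    seg_age, seg_dt = [], []
    starts, nsegs, rr, ss, dead, dage, prof, pers = [], [], [], [], [], [], [], []
    pos = 0
    positions = panel.reset_index(drop=True) \
        .sort_values(["person_id", "age"], kind="stable").index.to_numpy()
    pid_arr = panel["person_id"].to_numpy()
    age_arr = panel["age"].to_numpy(float)
    st_arr = panel["state"].to_numpy(int)
    kind_arr = panel["kind"].to_numpy()

    for a, b in zip(positions[:-1], positions[1:]):
        if pid_arr[a] != pid_arr[b]:
            continue
        x1, x2 = age_arr[a], age_arr[b]
        if kind_arr[a] == EXACT_DEATH:
            continue
        pts = grid_breakpoints(x1, x2, grid_step, x0)
        m = max(len(pts) - 1, 0)
        if m == 0:
            # zero-length interval: contributes log 1 or log 0 directly
            pts = np.array([x1, x1])
            m = 1
            seg_age.append(np.array([x1]))
            seg_dt.append(np.array([0.0]))
        else:
            seg_age.append(pts[:-1])
            seg_dt.append(np.diff(pts))
        starts.append(pos)
        nsegs.append(m)
        pos += m
        rr.append(st_arr[a] - 1)
        is_death = kind_arr[b] == EXACT_DEATH or st_arr[b] == DEAD
        dead.append(is_death)
        ss.append(0 if is_death else st_arr[b] - 1)
        dage.append(x2 if is_death else np.nan)
        prof.append(prof_idx[a])
        pers.append(pid_arr[a])

    if not starts:
        raise ValueError("panel contains no usable observation pairs")

    return PanelIntervals(
        seg_age=np.concatenate(seg_age), seg_dt=np.concatenate(seg_dt),
        itv_start=np.asarray(starts, np.int64),
        itv_nseg=np.asarray(nsegs, np.int64),
        itv_r=np.asarray(rr, np.int64), itv_s=np.asarray(ss, np.int64),
        itv_dead=np.asarray(dead, bool),
        itv_death_age=np.asarray(dage, float),
        itv_prof=np.asarray(prof, np.int64),
        profiles=profiles,
        person_of=np.asarray(pers, object),
        n_persons=len(pd.unique(pid_arr)), n_records=len(panel),
        grid_step=grid_step, x0=x0)


# ---------------------------------------------------------------------------
# numpy evaluation path

def _interval_probs_numpy(iv: PanelIntervals, params: GompertzParams
                          ) -> np.ndarray:
    """(n_intervals, 3, 3) living-block transition matrices per interval."""
    beta, xi, gamma, active = params.beta, params.xi, params.gamma, params.active
    profmult = np.exp(np.clip(iv.profiles @ gamma.T, -_LP_CLIP, _LP_CLIP))
    seg_prof = np.repeat(iv.itv_prof, iv.itv_nseg)
    lp = beta + np.outer(iv.seg_age - params.x0, xi)
    q = np.exp(np.clip(lp, -_LP_CLIP, _LP_CLIP)) * profmult[seg_prof]
    q = np.where(active, q, 0.0)
    A = np.zeros((len(iv.seg_age), 3, 3))
    for k in range(9):
        r, s = _TR_R[k], _TR_S[k]
        if s < 3:
            A[:, r, s] = q[:, k]
        A[:, r, r] -= q[:, k]
    E = expm_batch(A * iv.seg_dt[:, None, None])
    nI = len(iv.itv_start)
    P = np.broadcast_to(np.eye(3), (nI, 3, 3)).copy()
    max_nseg = int(iv.itv_nseg.max())
    for j in range(max_nseg):
        sel = iv.itv_nseg > j
        P[sel] = P[sel] @ E[iv.itv_start[sel] + j]
    return P


def _contributions_numpy(iv: PanelIntervals, params: GompertzParams
                         ) -> np.ndarray:
    P = _interval_probs_numpy(iv, params)
    out = np.empty(len(iv.itv_start))
    alive = ~iv.itv_dead
    with np.errstate(divide="ignore"):
        out[alive] = np.log(P[alive, iv.itv_r[alive], iv.itv_s[alive]])
        if iv.itv_dead.any():
            d = iv.itv_dead
            zd = iv.profiles[iv.itv_prof[d]]
            lp = (params.beta[_TR_TO_DEAD]
                  + np.outer(iv.itv_death_age[d] - params.x0,
                             params.xi[_TR_TO_DEAD])
                  + zd @ params.gamma[_TR_TO_DEAD].T)
            qd = np.exp(np.clip(lp, -_LP_CLIP, _LP_CLIP))
            qd = np.where(params.active[_TR_TO_DEAD], qd, 0.0)
            dens = np.einsum("ij,ij->i", P[d, iv.itv_r[d], :], qd)
            out[d] = np.log(dens)
    return out


# ---------------------------------------------------------------------------
# numba evaluation path (optional, numerically identical within roundoff)

try:  # pragma: no cover - exercised indirectly
    from ._kernel import loglik_kernel as _numba_kernel
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _numba_kernel = None
    HAVE_NUMBA = False


def _total_numba(iv: PanelIntervals, params: GompertzParams) -> tuple[float, int]:
    profmult = np.exp(np.clip(iv.profiles @ params.gamma.T, -_LP_CLIP, _LP_CLIP))
    profmult = profmult * params.active
    base = np.where(params.active,
                    np.exp(np.clip(params.beta, -_LP_CLIP, _LP_CLIP)), 0.0)
    return _numba_kernel(
        iv.seg_age, iv.seg_dt, iv.itv_start, iv.itv_nseg, iv.itv_r, iv.itv_s,
        iv.itv_dead, iv.itv_death_age, iv.itv_prof,
        base, params.xi, np.ascontiguousarray(profmult), params.x0)


def total_log_likelihood(panel_or_intervals, params: GompertzParams,
                         grid_step: float = 0.5,
                         covariate_columns=(), use_numba: bool | None = None
                         ) -> float:
    """Total panel log-likelihood; -inf if an impossible observation exists."""
    if isinstance(panel_or_intervals, PanelIntervals):
        iv = panel_or_intervals
    else:
        if len(panel_or_intervals) == 0:
            raise ValueError("empty panel")
        iv = compile_intervals(panel_or_intervals, covariate_columns,
                               grid_step, params.x0)
    if use_numba is None:
        use_numba = HAVE_NUMBA
    if use_numba and _numba_kernel is not None:
        total, nbad = _total_numba(iv, params)
        if nbad:
            _warn_underflow(iv, params)
        return float(total)
    contrib = _contributions_numpy(iv, params)
    if np.isneginf(contrib).any():
        _warn_underflow(iv, params, contrib)
    return float(contrib.sum())


def _warn_underflow(iv, params, contrib=None):
    if contrib is None:
        contrib = _contributions_numpy(iv, params)
    bad = np.nonzero(np.isneginf(contrib))[0]
    pids = sorted({str(iv.person_of[i]) for i in bad[:5]})
    warnings.warn(
        f"{len(bad)} observation pair(s) have probability 0 under the current "
        f"parameters (first persons: {', '.join(pids)})",
        LikelihoodUnderflowWarning, stacklevel=3)


def interval_contribution(rec1: PanelRecord, rec2: PanelRecord,
                          params: GompertzParams, grid_step: float = 0.5
                          ) -> float:
    """Log-likelihood term of one consecutive record pair of one person."""
    if rec2.age < rec1.age:
        raise ValueError("records out of age order")
    panel = pd.DataFrame(
        [(rec1.person_id, rec1.age, rec1.state, rec1.kind,
          rec1.gender01, rec1.education01),
         (rec2.person_id, rec2.age, rec2.state, rec2.kind,
          rec2.gender01, rec2.education01)],
        columns=["person_id", "age", "state", "kind", "gender01", "education01"])
    cols = ["gender01", "education01"][: params.n_covariates]
    iv = compile_intervals(panel, cols, grid_step, params.x0)
    contrib = _contributions_numpy(iv, params)
    if np.isneginf(contrib).any():
        _warn_underflow(iv, params, contrib)
    return float(contrib.sum())
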