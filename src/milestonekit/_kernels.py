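"""Numba-compiled inner loops for the toy dynamics engine.

All kernels work in package units (Å, ps, kcal/mol, amu).  Potentials and
collective variables are passed as small integer codes plus parameter
arrays (see :mod:`milestonekit.potentials`): cv_kind 0 is the first
coordinate, cv_kind 1 the radial distance from the origin.

Boundary crossings are detected by an end-of-step check (every
``check_interval`` steps): a CV value exactly on a level set counts as
crossed.  On a crossing the positions are restored to the previous step and
velocities are reversed (overdamped mode has no velocities, so restoration
plus a fresh noise draw on the next step is the overdamped analog).
"""

import numpy as np
from numba import njit

from .potentials import DOUBLE_WELL, FLAT, HARMONIC, RADIAL_HARMONIC, TABULATED_1D

_ = (FLAT,)  # codes are compile-time constants below


@njit(cache=True)
def _force(kind, p, x, f):
    d = x.shape[0]
    if kind == 0:  # flat
        for i in range(d):
            f[i] = 0.0
    elif kind == 1:  # harmonic
        k = p[0]
        for i in range(d):
            f[i] = -k * (x[i] - p[1 + i])
    elif kind == 2:  # double well, first coordinate
        h = p[0]
        a2 = p[1] * p[1]
        for i in range(d):
            f[i] = 0.0
        f[0] = -4.0 * h * x[0] * (x[0] * x[0] - a2) / (a2 * a2)
    elif kind == 3:  # radial harmonic
        k = p[0]
        r0 = p[1]
        r = 0.0
        for i in range(d):
            r += x[i] * x[i]
        r = np.sqrt(r)
        if r > 0.0:
            fr = -k * (r - r0) / r
            for i in range(d):
                f[i] = fr * x[i]
        else:
            for i in range(d):
                f[i] = 0.0
    else:  # tabulated 1-D
        x0 = p[0]
        dx = p[1]
        n = int(p[2])
        i = int(np.floor((x[0] - x0) / dx))
        if i < 0:
            i = 0
        if i > n - 2:
            i = n - 2
        slope = (p[3 + i + 1] - p[3 + i]) / dx
        for j in range(d):
            f[j] = 0.0
        f[0] = -slope


@njit(cache=True)
def _cv(cv_kind, x):
    if cv_kind == 0:
        return x[0]
    r = 0.0
    for i in range(x.shape[0]):
        r += x[i] * x[i]
    return np.sqrt(r)


@njit(cache=True)
def mmvt_overdamped(
    x_in,
    pot_kind,
    pot_params,
    cv_kind,
    lo,
    hi,
    D,
    kT,
    dt,
    n_steps,
    seed,
    check_interval,
    traj_stride,
    max_states,
):
    """Cell-confined overdamped (Brownian) dynamics with collision logging.

    Returns (collision side array [0 lower / 1 upper], collision times,
    final position, trajectory samples, n_traj, state sides, state times,
    state positions, n_states).
    """
    np.random.seed(seed)
    d = x_in.shape[0]
    x = x_in.copy()
    xprev = x.copy()
    xcross = x.copy()
    f = np.empty(d)
    mob_dt = D / kT * dt
    sig = np.sqrt(2.0 * D * dt)

    cap = 4096
    col_side = np.empty(cap, np.int8)
    col_time = np.empty(cap, np.float64)
    ncol = 0

    ntraj_cap = 0
    if traj_stride > 0:
        ntraj_cap = n_steps // traj_stride + 1
    traj = np.empty((ntraj_cap, d))
    ntraj = 0

    st_side = np.empty(max_states, np.int8)
    st_time = np.empty(max_states, np.float64)
    st_pos = np.empty((max_states, d))
    nst = 0

    for step in range(1, n_steps + 1):
        _force(pot_kind, pot_params, x, f)
        for i in range(d):
            xprev[i] = x[i]
            x[i] = x[i] + mob_dt * f[i] + sig * np.random.normal(0.0, 1.0)
        if step % check_interval == 0:
            cv = _cv(cv_kind, x)
            side = -1
            if cv >= hi:
                side = 1
            elif cv <= lo:
                side = 0
            if side >= 0:
                if ncol == cap:
                    cap *= 2
                    ns = np.empty(cap, np.int8)
                    nt = np.empty(cap, np.float64)
                    ns[:ncol] = col_side
                    nt[:ncol] = col_time
                    col_side = ns
                    col_time = nt
                col_side[ncol] = side
                col_time[ncol] = step * dt
                ncol += 1
                if nst < max_states:
                    st_side[nst] = side
                    st_time[nst] = step * dt
                    for i in range(d):
                        st_pos[nst, i] = x[i]
                    nst += 1
                for i in range(d):
                    x[i] = xprev[i]
        if traj_stride > 0 and step % traj_stride == 0:
            for i in range(d):
                traj[ntraj, i] = x[i]
            ntraj += 1

    return (
        col_side[:ncol],
        col_time[:ncol],
        x,
        traj[:ntraj],
        st_side[:nst],
        st_time[:nst],
        st_pos[:nst],
    )


@njit(cache=True, fastmath=True)
def mmvt_overdamped_1d(
    x0,
    pot_kind,
    pot_params,
    lo,
    hi,
    D,
    kT,
    dt,
    n_steps,
    seed,
    check_interval,
    traj_stride,
    max_states,
):
    """Scalar fast path of :func:`mmvt_overdamped` for 1-D systems.

    Identical semantics (same crossing rule, same bookkeeping); kept
    separate because the 1-D case carries the bulk of the oracle work and
    benefits ~5x from scalar arithmetic.
    """
    np.random.seed(seed)
    x = x0
    xprev = x0
    mob_dt = D / kT * dt
    sig = np.sqrt(2.0 * D * dt)

    cap = 4096
    col_side = np.empty(cap, np.int8)
    col_time = np.empty(cap, np.float64)
    ncol = 0

    ntraj_cap = 0
    if traj_stride > 0:
        ntraj_cap = n_steps // traj_stride + 1
    traj = np.empty((ntraj_cap, 1))
    ntraj = 0

    st_side = np.empty(max_states, np.int8)
    st_time = np.empty(max_states, np.float64)
    st_pos = np.empty((max_states, 1))
    nst = 0

    flat = pot_kind == 0
    for step in range(1, n_steps + 1):
        xprev = x
        if flat:
            x = x + sig * np.random.normal(0.0, 1.0)
        else:
            if pot_kind == 1:
                fx = -pot_params[0] * (x - pot_params[1])
            elif pot_kind == 2:
                a2 = pot_params[1] * pot_params[1]
                fx = -4.0 * pot_params[0] * x * (x * x - a2) / (a2 * a2)
            elif pot_kind == 3:
                r = np.abs(x)
                if r > 0.0:
                    fx = -pot_params[0] * (r - pot_params[1]) * (x / r)
                else:
                    fx = 0.0
            else:
                n = int(pot_params[2])
                i = int(np.floor((x - pot_params[0]) / pot_params[1]))
                if i < 0:
                    i = 0
                if i > n - 2:
                    i = n - 2
                fx = -(pot_params[3 + i + 1] - pot_params[3 + i]) / pot_params[1]
            x = x + mob_dt * fx + sig * np.random.normal(0.0, 1.0)
        if step % check_interval == 0:
            side = -1
            if x >= hi:
                side = 1
            elif x <= lo:
                side = 0
            if side >= 0:
                if ncol == cap:
                    cap *= 2
                    ns = np.empty(cap, np.int8)
                    nt = np.empty(cap, np.float64)
                    ns[:ncol] = col_side
                    nt[:ncol] = col_time
                    col_side = ns
                    col_time = nt
                col_side[ncol] = side
                col_time[ncol] = step * dt
                ncol += 1
                if nst < max_states:
                    st_side[nst] = side
                    st_time[nst] = step * dt
                    st_pos[nst, 0] = x
                    nst += 1
                x = xprev
        if traj_stride > 0 and step % traj_stride == 0:
            traj[ntraj, 0] = x
            ntraj += 1

    xout = np.empty(1)
    xout[0] = x
    return (
        col_side[:ncol],
        col_time[:ncol],
        xout,
        traj[:ntraj],
        st_side[:nst],
        st_time[:nst],
        st_pos[:nst],
    )


@njit(cache=True)
def mmvt_langevin(
    x_in,
    v_in,
    pot_kind,
    pot_params,
    cv_kind,
    lo,
    hi,
    friction,
    mass,
    kT_int,
    dt,
    n_steps,
    seed,
    check_interval,
    traj_stride,
    max_states,
):
    """Cell-confined Langevin (BAOAB) dynamics with velocity-reversal collisions.

    ``kT_int`` must already be in internal energy units (amu Å^2 ps^-2);
    forces from the potential (kcal/mol/Å) are converted with the 418.4
    factor inside.
    """
    np.random.seed(seed)
    KCAL = 418.4
    d = x_in.shape[0]
    x = x_in.copy()
    v = v_in.copy()
    xprev = x.copy()
    vprev = v.copy()
    f = np.empty(d)
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(kT_int / mass * (1.0 - c1 * c1))

    cap = 4096
    col_side = np.empty(cap, np.int8)
    col_time = np.empty(cap, np.float64)
    ncol = 0

    ntraj_cap = 0
    if traj_stride > 0:
        ntraj_cap = n_steps // traj_stride + 1
    traj = np.empty((ntraj_cap, d))
    ntraj = 0

    st_side = np.empty(max_states, np.int8)
    st_time = np.empty(max_states, np.float64)
    st_pos = np.empty((max_states, d))
    st_vel = np.empty((max_states, d))
    nst = 0

    _force(pot_kind, pot_params, x, f)
    for step in range(1, n_steps + 1):
        for i in range(d):
            xprev[i] = x[i]
            vprev[i] = v[i]
        # B A O A B splitting
        for i in range(d):
            v[i] += 0.5 * dt * f[i] * KCAL / mass
            x[i] += 0.5 * dt * v[i]
        for i in range(d):
            v[i] = c1 * v[i] + c2 * np.random.normal(0.0, 1.0)
            x[i] += 0.5 * dt * v[i]
        _force(pot_kind, pot_params, x, f)
        for i in range(d):
            v[i] += 0.5 * dt * f[i] * KCAL / mass
        if step % check_interval == 0:
            cv = _cv(cv_kind, x)
            side = -1
            if cv >= hi:
                side = 1
            elif cv <= lo:
                side = 0
            if side >= 0:
                if ncol == cap:
                    cap *= 2
                    ns = np.empty(cap, np.int8)
                    nt = np.empty(cap, np.float64)
                    ns[:ncol] = col_side
                    nt[:ncol] = col_time
                    col_side = ns
                    col_time = nt
                col_side[ncol] = side
                col_time[ncol] = step * dt
                ncol += 1
                if nst < max_states:
                    st_side[nst] = side
                    st_time[nst] = step * dt
                    for i in range(d):
                        st_pos[nst, i] = x[i]
                        st_vel[nst, i] = v[i]
                    nst += 1
                # restore previous positions, reverse velocities
                for i in range(d):
                    x[i] = xprev[i]
                    v[i] = -vprev[i]
                _force(pot_kind, pot_params, x, f)
        if traj_stride > 0 and step % traj_stride == 0:
            for i in range(d):
                traj[ntraj, i] = x[i]
            ntraj += 1

    return (
        col_side[:ncol],
        col_time[:ncol],
        x,
        v,
        traj[:ntraj],
        st_side[:nst],
        st_time[:nst],
        st_pos[:nst],
        st_vel[:nst],
    )


@njit(cache=True)
def first_hitting_overdamped(
    x_in,
    pot_kind,
    pot_params,
    cv_kind,
    lo,
    hi,
    has_lo,
    has_hi,
    D,
    kT,
    dt,
    max_steps,
    seed,
    lower_wall,
    has_lower_wall,
):
    """Overdamped trajectory until it first touches an absorbing level.

    Returns (side, n_steps): side 0 = lower level, 1 = upper level,
    -1 = max_steps exhausted.  ``lower_wall`` (cv_kind 0 only) reflects the
    first coordinate: an explicit reflecting end of the toy domain.
    """
    np.random.seed(seed)
    d = x_in.shape[0]
    x = x_in.copy()
    f = np.empty(d)
    mob_dt = D / kT * dt
    sig = np.sqrt(2.0 * D * dt)
    for step in range(1, max_steps + 1):
        _force(pot_kind, pot_params, x, f)
        for i in range(d):
            x[i] = x[i] + mob_dt * f[i] + sig * np.random.normal(0.0, 1.0)
        if has_lower_wall and x[0] < lower_wall:
            x[0] = 2.0 * lower_wall - x[0]
        cv = _cv(cv_kind, x)
        if has_hi and cv >= hi:
            return 1, step
        if has_lo and cv <= lo:
            return 0, step
    return -1, max_steps


@njit(cache=True)
def smd_overdamped(
    x_in,
    pot_kind,
    pot_params,
    cv_kind,
    k_spring,
    lam_start,
    lam_end,
    D,
    kT,
    dt,
    n_steps,
    seed,
    record_stride,
):
    """Overdamped dynamics with a moving harmonic restraint on the CV.

    The restraint centre moves linearly from ``lam_start`` to ``lam_end``
    over the run.  Returns recorded (positions, cv values) every
    ``record_stride`` steps plus the final position.
    """
    np.random.seed(seed)
    d = x_in.shape[0]
    x = x_in.copy()
    f = np.empty(d)
    mob_dt = D / kT * dt
    sig = np.sqrt(2.0 * D * dt)
    ncap = n_steps // record_stride + 1
    pos = np.empty((ncap, d))
    cvs = np.empty(ncap)
    nrec = 0
    for step in range(1, n_steps + 1):
        _force(pot_kind, pot_params, x, f)
        lam = lam_start + (lam_end - lam_start) * step / n_steps
        cv = _cv(cv_kind, x)
        # restraint force: -k (cv - lam) * dcv/dx
        if cv_kind == 0:
            f[0] += -k_spring * (cv - lam)
        else:
            if cv > 0.0:
                fr = -k_spring * (cv - lam) / cv
                for i in range(d):
                    f[i] += fr * x[i]
        for i in range(d):
            x[i] = x[i] + mob_dt * f[i] + sig * np.random.normal(0.0, 1.0)
        if step % record_stride == 0:
            for i in range(d):
                pos[nrec, i] = x[i]
            cvs[nrec] = _cv(cv_kind, x)
            nrec += 1
    return pos[:nrec], cvs[:nrec], x


@njit(cache=True)
def overdamped_trajectory(x_in, pot_kind, pot_params, D, kT, dt, n_steps, seed, stride):
    """Plain (unconfined) overdamped run; brute-force oracle helper."""
    np.random.seed(seed)
    d = x_in.shape[0]
    x = x_in.copy()
    f = np.empty(d)
    mob_dt = D / kT * dt
    sig = np.sqrt(2.0 * D * dt)
    ncap = n_steps // stride + 1
    traj = np.empty((ncap, d))
    nrec = 0
    for step in range(1, n_steps + 1):
        _force(pot_kind, pot_params, x, f)
        for i in range(d):
            x[i] = x[i] + mob_dt * f[i] + sig * np.random.normal(0.0, 1.0)
        if step % stride == 0:
            for i in range(d):
                traj[nrec, i] = x[i]
            nrec += 1
    return traj[:nrec], x


@njit(cache=True)
def bd_hit_fraction(n_traj, start_radius, r_reaction, r_escape, D, dt_max, seed, max_steps):
    """Free-diffusion trajectories from a spherical shell: count reactions.

    Each trajectory starts uniformly oriented at ``start_radius`` and runs
    until it reaches ``r_reaction`` (hit) or ``r_escape`` (escape).  The
    timestep shrinks near the absorbing spheres so that one step's noise is
    small compared to the remaining gap; within a tolerance of 1e-3 of the
    inter-sphere distance a trajectory is declared absorbed (the adaptive
    walk contracts the gap geometrically, so the induced bias is of the same
    1e-3 relative order).
    """
    np.random.seed(seed)
    hits = 0
    x = np.empty(3)
    tol = 1e-3 * (r_escape - r_reaction)
    for _ in range(n_traj):
        # uniform point on the start sphere
        nrm = 0.0
        while nrm == 0.0:
            for i in range(3):
                x[i] = np.random.normal(0.0, 1.0)
            nrm = np.sqrt(x[0] ** 2 + x[1] ** 2 + x[2] ** 2)
        for i in range(3):
            x[i] *= start_radius / nrm
        for _step in range(max_steps):
            r = np.sqrt(x[0] ** 2 + x[1] ** 2 + x[2] ** 2)
            if r <= r_reaction + tol:
                hits += 1
                break
            if r >= r_escape - tol:
                break
            gap = r - r_reaction
            gap2 = r_escape - r
            if gap2 < gap:
                gap = gap2
            dt = (0.2 * gap) ** 2 / (2.0 * D)
            if dt > dt_max:
                dt = dt_max
            sig = np.sqrt(2.0 * D * dt)
            for i in range(3):
                x[i] += sig * np.random.normal(0.0, 1.0)
    return hits
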