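"""Numba kernels for the DDM: forward Kolmogorov solver and path simulation.

The solver integrates the Fokker-Planck equation

    dp/dt = -v dp/dx + (sigma^2/2) d2p/dx2

on a fixed spatial grid spanning [-a, a] with absorbing nodes tracking the
collapsing bound +/-B(t).  Time stepping is Crank-Nicolson with a short
fully-implicit (Rannacher) start-up to damp oscillations from the delta
initial condition.  Probability absorbed at each boundary per step is
split according to one-sided second-order boundary fluxes, so total mass
(upper + lower + surviving) is conserved to machine precision.
"""

import numpy as np
from numba import njit

__all__ = ["fpt_kernel", "simulate_paths", "interp_loglik"]


@njit(cache=True)
def interp_loglik(rts, t0, dt, g, floor):
    """Sum of log densities, linear interpolation on the uniform grid.

    ``g[i]`` is the density at t = (i + 1) * dt; values outside the grid
    contribute the floor.
    """
    total = 0.0
    n = len(g)
    for i in range(len(rts)):
        pos = (rts[i] - t0) / dt - 1.0
        if pos < 0.0 or pos >= n - 1:
            d = 0.0
        else:
            j = int(pos)
            w = pos - j
            d = g[j] * (1.0 - w) + g[j + 1] * w
        if d < floor:
            d = floor
        total += np.log(d)
    return total


@njit(cache=True)
def fpt_kernel(v, a, b_collapse, b_t, z, sigma, dt, nx, nt):
    """Defective first-passage densities under collapsing bounds.

    Returns (g_up, g_lo, survival) where g_up[i] and g_lo[i] are the
    densities (1/s) of absorption at the upper and lower bound in the
    interval (i*dt, (i+1)*dt].

    The equation is solved in bound-normalized coordinates y = x / B(t),
    where the absorbing boundaries sit at the fixed nodes y = +/-1 and
    the collapse appears as an outward linear drift y * b_collapse and a
    growing effective diffusion sigma / B(t).  This keeps the solution
    smooth in all parameters (no moving-boundary staircase), which
    matters for derivative-based fitting.
    """
    dy = 2.0 / (nx - 1)
    q = np.zeros(nx)
    # delta at y0 = z / a, split over the two neighboring nodes
    pos = (z / a + 1.0) / dy
    j0 = int(np.floor(pos))
    w = pos - j0
    if j0 < 0:
        j0, w = 0, 0.0
    if j0 >= nx - 1:
        j0, w = nx - 2, 1.0
    q[j0] += (1.0 - w) / dy
    q[j0 + 1] += w / dy

    g_up = np.zeros(nt)
    g_lo = np.zeros(nt)

    cp = np.zeros(nx)
    dp_ = np.zeros(nx)

    mass = 0.0
    for j in range(nx):
        mass += q[j]
    mass *= dy

    b_floor = 0.025 * a  # below this the bound is numerically collapsed

    for n in range(nt):
        t_old = n * dt
        t_new = t_old + dt
        t_mid = t_old + 0.5 * dt
        b_mid = a * np.exp(-b_collapse * max(0.0, t_mid - b_t))
        b_end = a * np.exp(-b_collapse * max(0.0, t_new - b_t))

        if b_end < b_floor:
            # bound effectively gone: absorb everything, split by side
            up = 0.0
            lo_m = 0.0
            mid = (nx - 1) // 2
            for j in range(nx):
                if j > mid:
                    up += q[j]
                elif j < mid:
                    lo_m += q[j]
                else:
                    up += 0.5 * q[j]
                    lo_m += 0.5 * q[j]
                q[j] = 0.0
            g_up[n] = up * dy / dt
            g_lo[n] = lo_m * dy / dt
            return g_up, g_lo, 0.0

        # fraction of this step spent past the collapse onset (smooth in b_t)
        frac = (t_new - b_t) / dt
        if frac < 0.0:
            frac = 0.0
        elif frac > 1.0:
            frac = 1.0
        c_n = b_collapse * frac

        s2 = (sigma / b_mid) * (sigma / b_mid)
        vb = v / b_mid
        D2 = 0.5 * s2 / (dy * dy)

        theta = 1.0 if n < 4 else 0.5  # Rannacher start-up
        lo = 1
        hi = nx - 2

        # advection coefficient at node j is alpha + beta * j
        alpha = (vb - c_n) / (2.0 * dy)
        beta = 0.5 * c_n
        omt = dt * (1.0 - theta)
        tdt = dt * theta
        c0 = -2.0 * D2 - c_n
        b0 = 1.0 + omt * c0
        a0 = 1.0 - tdt * c0

        # fused pass: rhs = (I + dt(1-theta)L) q  and Thomas forward sweep
        # of A = I - dt*theta*L (q = 0 at both ends)
        adv = alpha + beta * lo
        inv = 1.0 / a0
        cp[lo] = -tdt * (D2 - adv) * inv
        dp_[lo] = (b0 * q[lo] + omt * (D2 - adv) * q[lo + 1]) * inv
        for j in range(lo + 1, hi + 1):
            adv += beta
            cm = D2 + adv
            cpl = D2 - adv
            right = q[j + 1] if j < hi else 0.0
            rhs = omt * (cm * q[j - 1] + cpl * right) + b0 * q[j]
            am = -tdt * cm
            inv = 1.0 / (a0 - am * cp[j - 1])
            cp[j] = -tdt * cpl * inv
            dp_[j] = (rhs - am * dp_[j - 1]) * inv

        # fused back-substitution, negativity clamp, and mass sum
        x = dp_[hi]
        if x < 0.0:
            x = 0.0
        q[hi] = x
        new_mass = x
        for j in range(hi - 1, lo - 1, -1):
            x = dp_[j] - cp[j] * q[j + 1]
            if x < 0.0:
                x = 0.0
            q[j] = x
            new_mass += x
        new_mass *= dy

        loss = mass - new_mass
        if loss < 0.0:
            loss = 0.0
        # one-sided second-order diffusive fluxes at the boundaries (q=0 there)
        f_up = 0.5 * s2 * (4.0 * q[hi] - q[hi - 1]) / (2.0 * dy)
        f_lo = 0.5 * s2 * (4.0 * q[lo] - q[lo + 1]) / (2.0 * dy)
        if f_up < 0.0:
            f_up = 0.0
        if f_lo < 0.0:
            f_lo = 0.0
        tot = f_up + f_lo
        share_up = f_up / tot if tot > 0.0 else 0.5
        g_up[n] = loss * share_up / dt
        g_lo[n] = loss * (1.0 - share_up) / dt
        mass = new_mass

    return g_up, g_lo, mass


@njit(cache=True)
def simulate_paths(n, v, a, b_collapse, b_t, z, sigma, dt, t_max, seed):
    """Euler-Maruyama sample paths to absorption at +/-B(t).

    Includes the Brownian-bridge crossing correction: between step
    endpoints that both lie inside the bounds, the path may still have
    crossed, with probability exp(-2 d_old d_new / (sigma^2 dt)) for
    boundary distances d_old, d_new.  This removes the O(sqrt(dt))
    boundary bias of the plain Euler scheme.

    Returns (choice, decision_time) where choice is +1 for the upper
    bound, -1 for the lower bound, and 0 for non-absorbed paths.
    """
    np.random.seed(seed)
    choices = np.zeros(n, dtype=np.int8)
    times = np.zeros(n)
    sqdt = np.sqrt(dt)
    s2dt = sigma * sigma * dt
    n_steps = int(t_max / dt)
    bnds = np.empty(n_steps + 1)
    for s in range(n_steps + 1):
        bnds[s] = a * np.exp(-b_collapse * max(0.0, s * dt - b_t))
    for i in range(n):
        x = z
        t = 0.0
        absorbed = False
        for s in range(n_steps):
            t = (s + 1) * dt
            b_old = bnds[s]
            b_new = bnds[s + 1]
            x_new = x + v * dt + sigma * sqdt * np.random.randn()
            if x_new >= b_new:
                choices[i] = 1
                times[i] = t
                absorbed = True
                break
            if x_new <= -b_new:
                choices[i] = -1
                times[i] = t
                absorbed = True
                break
            # bridge crossing of the upper bound
            du = (b_old - x) * (b_new - x_new)
            if du < 20.0 * s2dt:
                if np.random.rand() < np.exp(-2.0 * du / s2dt):
                    choices[i] = 1
                    times[i] = t
                    absorbed = True
                    break
            # bridge crossing of the lower bound
            dl = (x + b_old) * (x_new + b_new)
            if dl < 20.0 * s2dt:
                if np.random.rand() < np.exp(-2.0 * dl / s2dt):
                    choices[i] = -1
                    times[i] = t
                    absorbed = True
                    break
            x = x_new
        if not absorbed:
            choices[i] = 0
            times[i] = t_max
    return choices, times
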