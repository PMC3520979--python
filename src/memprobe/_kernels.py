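"""Numba inner loop for the Brownian photon-trace simulator.

Random numbers are generated outside the kernel in bulk (numpy SFC64
streams, the fastest bit generator available) and consumed here, so
reproducibility depends only on the numpy Generator contract.  The kernel
scales unit-normal steps by the per-bin RMS displacement, wraps positions
periodically, propagates the blinking/bleaching state machine and
accumulates the summed Gaussian detection profile per bin.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def propagate_block(pos, state, steps, sigma, n_mobile,
                    u_trip, u_bleach, half, inv_w0sq, inv_wzsq,
                    p_b2d, p_d2b, p_bleach, profile_out):
    """Advance one species over a block of time bins.

    pos : (n, 3) positions (µm), updated in place.
    state : (n,) int8, 0 bright / 1 triplet-dark / 2 bleached, in place.
    steps : (nt, n, n_mobile) unit-normal draws; dummy (1,1,1) if sigma == 0.
    u_trip, u_bleach : (nt, n) uniforms, dummy (1,1) when disabled.
    profile_out : (nt,) receives Σ_i W(r_i) over bright particles.
    """
    nt = profile_out.shape[0]
    n = pos.shape[0]
    use_trip = (p_b2d > 0.0) or (p_d2b > 0.0)
    use_bleach = p_bleach > 0.0
    mobile = sigma > 0.0
    hx, hy, hz = half[0], half[1], half[2]
    for t in range(nt):
        acc = 0.0
        for i in range(n):
            x = pos[i, 0]
            y = pos[i, 1]
            z = pos[i, 2]
            if mobile:
                x += sigma * steps[t, i, 0]
                y += sigma * steps[t, i, 1]
                # periodic minimum-image wrap into [-h, h)
                x -= 2.0 * hx * np.floor((x + hx) / (2.0 * hx))
                y -= 2.0 * hy * np.floor((y + hy) / (2.0 * hy))
                pos[i, 0] = x
                pos[i, 1] = y
                if n_mobile == 3:
                    z += sigma * steps[t, i, 2]
                    z -= 2.0 * hz * np.floor((z + hz) / (2.0 * hz))
                    pos[i, 2] = z
            s = state[i]
            if use_bleach and s != 2 and u_bleach[t, i] < p_bleach:
                s = 2
                state[i] = s
            elif use_trip:
                u = u_trip[t, i]
                if s == 0:
                    if u < p_b2d:
                        s = 1
                        state[i] = s
                elif s == 1:
                    if u < p_d2b:
                        s = 0
                        state[i] = s
            if s == 0:
                acc += np.exp(-2.0 * (x * x + y * y) * inv_w0sq
                              - 2.0 * z * z * inv_wzsq)
        profile_out[t] = acc
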