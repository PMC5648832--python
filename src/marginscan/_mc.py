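"""Numba kernel for Monte Carlo photon transport in layered turbid media.

Standard weighted hop-drop-spin random walk (MCML-style): exponential
path-length sampling, absorption by weight at interaction sites,
Henyey-Greenstein scattering, Fresnel reflection/refraction at the top
surface and at internal index mismatches, Russian roulette termination.
Serial and explicitly seeded, so runs are bit-reproducible.

Weight bookkeeping is exact: every unit of launched weight ends in one of
the ledger buckets (reflected, absorbed, transmitted below the depth
cutoff, roulette-killed, step-capped), with the weight created by
roulette survival boosts recorded separately so the balance closes to
floating-point precision.
"""

import numpy as np
from numba import njit

# ledger indices
REFLECTED, ABSORBED, TRANSMITTED, ROULETTE_KILLED, STEP_KILLED, ROULETTE_BOOST = range(6)


@njit(cache=True, fastmath=True)
def mc_kernel(
    n_photons,
    seed,
    z_bounds,      # (n_layers+1,) cumulative layer bottoms, z_bounds[0] == 0
    mua,           # (n_layers,) absorption / mm
    mus,           # (n_layers,) scattering / mm
    g,             # (n_layers,) anisotropy
    nidx,          # (n_layers,) refractive index
    n_out,         # refractive index above the surface
    offsets,       # (n_ann,) annulus center offsets, mm
    half_width,    # annulus half width, mm
    w_min,         # roulette threshold
    p_survive,     # roulette survival probability
    max_steps,     # per-photon interaction cap
):
    np.random.seed(seed)
    n_ann = offsets.shape[0]
    det_w = np.zeros(n_ann)
    ledger = np.zeros(6)
    cap = n_photons
    det_idx = np.empty(cap, np.int32)
    det_weight = np.empty(cap)
    det_depth = np.empty(cap)
    n_det = 0

    z_cut = z_bounds[-1]
    n_layers = mua.shape[0]

    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        layer = 0
        dmax = 0.0
        steps = 0
        alive = True

        while alive:
            mut = mua[layer] + mus[layer]
            s_ = -np.log(np.random.random())  # dimensionless step

            # --- hop, possibly across boundaries ---
            while True:
                step = s_ / mut
                if uz < 0.0:
                    db = (z - z_bounds[layer]) / (-uz)
                elif uz > 0.0:
                    db = (z_bounds[layer + 1] - z) / uz
                else:
                    db = 1e30
                if db < step:
                    x += ux * db
                    y += uy * db
                    z += uz * db
                    if z > dmax:
                        dmax = z
                    s_ -= db * mut
                    if uz < 0.0 and layer == 0:
                        # top surface: Fresnel escape or internal reflection
                        ci = -uz
                        n1 = nidx[0]
                        st2 = (n1 / n_out) * (n1 / n_out) * (1.0 - ci * ci)
                        if st2 >= 1.0:
                            refl = 1.0
                        else:
                            ct = np.sqrt(1.0 - st2)
                            rs = (n1 * ci - n_out * ct) / (n1 * ci + n_out * ct)
                            rp = (n1 * ct - n_out * ci) / (n1 * ct + n_out * ci)
                            refl = 0.5 * (rs * rs + rp * rp)
                        if np.random.random() < refl:
                            uz = -uz
                            z = 0.0
                        else:
                            ledger[REFLECTED] += w
                            r = np.sqrt(x * x + y * y)
                            for k in range(n_ann):
                                if abs(r - offsets[k]) <= half_width:
                                    det_w[k] += w
                                    if n_det < cap:
                                        det_idx[n_det] = k
                                        det_weight[n_det] = w
                                        det_depth[n_det] = dmax
                                        n_det += 1
                                    break
                            alive = False
                            break
                    elif uz > 0.0 and layer == n_layers - 1:
                        # below the semi-infinite truncation depth
                        ledger[TRANSMITTED] += w
                        alive = False
                        break
                    else:
                        # internal boundary
                        nxt = layer - 1 if uz < 0.0 else layer + 1
                        n1 = nidx[layer]
                        n2 = nidx[nxt]
                        if n1 == n2:
                            layer = nxt
                        else:
                            ci = abs(uz)
                            st2 = (n1 / n2) * (n1 / n2) * (1.0 - ci * ci)
                            if st2 >= 1.0:
                                uz = -uz
                            else:
                                ct = np.sqrt(1.0 - st2)
                                rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
                                rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
                                refl = 0.5 * (rs * rs + rp * rp)
                                if np.random.random() < refl:
                                    uz = -uz
                                else:
                                    ratio = n1 / n2
                                    ux *= ratio
                                    uy *= ratio
                                    uz = ct if uz > 0.0 else -ct
                                    layer = nxt
                        if alive:
                            mut = mua[layer] + mus[layer]
                        continue
                else:
                    x += ux * step
                    y += uy * step
                    z += uz * step
                    if z > dmax:
                        dmax = z
                    break
            if not alive:
                break

            # --- drop ---
            dw = w * mua[layer] / mut
            ledger[ABSORBED] += dw
            w -= dw
            if w <= 0.0:
                break

            # --- roulette ---
            if w < w_min:
                if np.random.random() < p_survive:
                    ledger[ROULETTE_BOOST] += w * (1.0 / p_survive - 1.0)
                    w /= p_survive
                else:
                    ledger[ROULETTE_KILLED] += w
                    break

            steps += 1
            if steps >= max_steps:
                ledger[STEP_KILLED] += w
                break

            # --- spin (Henyey-Greenstein) ---
            gg = g[layer]
            if gg == 0.0:
                cost = 2.0 * np.random.random() - 1.0
            else:
                tmp = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * np.random.random())
                cost = (1.0 + gg * gg - tmp * tmp) / (2.0 * gg)
                if cost > 1.0:
                    cost = 1.0
                elif cost < -1.0:
                    cost = -1.0
            sint = np.sqrt(1.0 - cost * cost)
            phi = 2.0 * np.pi * np.random.random()
            cosp = np.cos(phi)
            sinp = np.sin(phi)
            if abs(uz) > 0.99999:
                ux = sint * cosp
                uy = sint * sinp
                uz = cost if uz > 0.0 else -cost
            else:
                tmp = np.sqrt(1.0 - uz * uz)
                ux_n = sint * (ux * uz * cosp - uy * sinp) / tmp + ux * cost
                uy_n = sint * (uy * uz * cosp + ux * sinp) / tmp + uy * cost
                uz_n = -sint * cosp * tmp + uz * cost
                norm = np.sqrt(ux_n * ux_n + uy_n * uy_n + uz_n * uz_n)
                ux = ux_n / norm
                uy = uy_n / norm
                uz = uz_n / norm

    return det_w, ledger, det_idx[:n_det], det_weight[:n_det], det_depth[:n_det]
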