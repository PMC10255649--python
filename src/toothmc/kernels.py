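"""Numba transport kernel: photon-packet propagation through a voxel grid.

One compiled routine (:func:`propagate_one`) is used both for the forward run
and for photon replay, so a replayed packet follows bit-for-bit the same
random-number stream and voxel traversal as the packet that was detected.

Physics implemented per packet:

* launch from a Gaussian beam (1/e^2 radius ``beam_r``, truncated at twice
  that radius) on the source face, with the deterministic specular Fresnel
  loss applied at the air-tissue interface when surface reflection (WSR) is
  enabled;
* free paths sampled as a dimensionless optical depth ``tau = -ln(u)``
  consumed across voxels (chord length times local mu_t), which reduces to
  ``-ln(u)/mu_t`` in homogeneous regions;
* exact face-to-face voxel stepping: the chord in every voxel is the exact
  ray segment, accumulated into per-tissue partial pathlengths and elapsed
  time (chord * n / c);
* implicit capture at interaction sites (deposit ``w*mu_a/mu_t`` into the
  fluence map, survive with ``w*mu_s/mu_t``), HG deflection, uniform azimuth;
* unpolarized Fresnel reflect/refract decisions at voxel faces where the
  refractive index changes, skipped entirely when WSR is off or the indices
  match (so matched-index WSR and W/OSR runs consume identical streams);
* detection when a packet transmits out of tissue through a face lying on a
  detector disc; Russian roulette below a weight threshold; a 1 ns time gate.

Per-photon random streams are counter-based (splitmix64 keyed by
``(seed, photon index)``) so any single packet can be replayed in isolation.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .optics import _fresnel_reflectance, _hg_cos_theta, _scatter_direction

C_MM_PER_NS = 299.792458

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_STREAM = np.uint64(0xD1342543DE82EF95)

# terminal status codes
STATUS_ABSORBED = 0
STATUS_DETECTED = 1
STATUS_ESCAPED = 2
STATUS_TIME_EXPIRED = 3
STATUS_STEP_LIMIT = 4

# slots of the per-photon output vector
OUT_STATUS = 0
OUT_DET = 1
OUT_W = 2
OUT_T = 3
OUT_PP = 4       # 4,5,6 : enamel, dentin, pulp pathlength (mm)
OUT_NSC = 7      # 7,8,9 : scattering counts per tissue
OUT_ABSORBED = 10
OUT_ESCAPED = 11
OUT_RESIDUAL = 12
OUT_SIZE = 13


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _u01(state):
    """Advance the splitmix64 state; return (state, uniform in (0, 1))."""
    state = state + _GOLDEN
    z = _mix64(state)
    u = (np.float64(z >> np.uint64(11)) + 0.5) * (1.0 / 9007199254740992.0)
    return state, u


@njit(cache=True, inline="always")
def photon_stream_state(seed, j):
    """Initial RNG state of photon ``j`` under run seed ``seed``."""
    return _mix64(_mix64(np.uint64(seed) + _GOLDEN) ^ ((np.uint64(j) + np.uint64(1)) * _STREAM))


@njit(cache=True)
def propagate_one(
    state,
    labels, pitch, ox, oy, oz,
    mua, mus, g_arr, nref, ambient_n,
    sx, sy, sz, dx0, dy0, dz0, beam_r, src_axis,
    det_axis, det_plane, det_c1, det_c2, det_r2,
    wsr, t_end, roulette_thr, roulette_p, max_steps,
    fluence, deposit_fluence,
    acc_w, path_acc, nsc_acc, accumulate,
    out,
):
    """Propagate a single packet from launch to a terminal event.

    Fills ``out`` (length OUT_SIZE) with the terminal status, exit weight and
    time, per-tissue pathlengths and scattering counts, and the packet's
    contributions to the absorbed / escaped / residual weight ledger.  When
    ``accumulate`` is true, per-voxel chord lengths and scattering events are
    added to ``path_acc`` / ``nsc_acc`` with weight ``acc_w`` (photon replay).
    """
    for k in range(OUT_SIZE):
        out[k] = 0.0

    nx, ny, nz = labels.shape

    # --- launch: Gaussian beam sample in the lateral plane of src_axis ---
    r = 0.0
    for _ in range(64):
        state, u = _u01(state)
        r = beam_r * math.sqrt(-0.5 * math.log(u))
        if r <= 2.0 * beam_r:
            break
    state, u = _u01(state)
    phi = 2.0 * math.pi * u
    e1 = r * math.cos(phi)
    e2 = r * math.sin(phi)
    px, py, pz = sx, sy, sz
    if src_axis == 0:
        py += e1
        pz += e2
    elif src_axis == 1:
        px += e1
        pz += e2
    else:
        px += e1
        py += e2
    ux, uy, uz = dx0, dy0, dz0

    # entry voxel indices; the position sits exactly on the source plane
    if src_axis == 0:
        ix = int(round((px - ox) / pitch)) if ux > 0 else int(round((px - ox) / pitch)) - 1
        iy = int(math.floor((py - oy) / pitch))
        iz = int(math.floor((pz - oz) / pitch))
    elif src_axis == 1:
        ix = int(math.floor((px - ox) / pitch))
        iy = int(round((py - oy) / pitch)) if uy > 0 else int(round((py - oy) / pitch)) - 1
        iz = int(math.floor((pz - oz) / pitch))
    else:
        ix = int(math.floor((px - ox) / pitch))
        iy = int(math.floor((py - oy) / pitch))
        iz = int(round((pz - oz) / pitch)) if uz > 0 else int(round((pz - oz) / pitch)) - 1
    if ix < 0 or iy < 0 or iz < 0 or ix >= nx or iy >= ny or iz >= nz:
        out[OUT_STATUS] = STATUS_ESCAPED
        out[OUT_ESCAPED] = 1.0
        return

    w = 1.0
    lab = labels[ix, iy, iz]
    if wsr and nref[lab] != ambient_n:
        if src_axis == 0:
            ci = abs(ux)
        elif src_axis == 1:
            ci = abs(uy)
        else:
            ci = abs(uz)
        rspec = _fresnel_reflectance(ambient_n, nref[lab], ci)
        out[OUT_ESCAPED] += rspec  # specular loss returns to the ambient air
        w -= rspec

    t = 0.0
    pp1 = pp2 = pp3 = 0.0
    ns1 = ns2 = ns3 = 0.0

    state, u = _u01(state)
    tau = -math.log(u)
    steps = 0
    status = STATUS_STEP_LIMIT
    det_id = -1.0

    while steps < max_steps:
        steps += 1
        lab = labels[ix, iy, iz]
        mt = mua[lab] + mus[lab]
        nloc = nref[lab]

        # distance to the next voxel face along the current direction
        big = 1e300
        if ux > 0.0:
            tx = (ox + (ix + 1) * pitch - px) / ux
        elif ux < 0.0:
            tx = (ox + ix * pitch - px) / ux
        else:
            tx = big
        if uy > 0.0:
            ty = (oy + (iy + 1) * pitch - py) / uy
        elif uy < 0.0:
            ty = (oy + iy * pitch - py) / uy
        else:
            ty = big
        if uz > 0.0:
            tz = (oz + (iz + 1) * pitch - pz) / uz
        elif uz < 0.0:
            tz = (oz + iz * pitch - pz) / uz
        else:
            tz = big
        dbound = tx
        axis = 0
        if ty < dbound:
            dbound = ty
            axis = 1
        if tz < dbound:
            dbound = tz
            axis = 2
        if dbound < 0.0:
            dbound = 0.0

        dint = tau / mt
        interact = dint <= dbound
        dmove = dint if interact else dbound

        # time gate: truncate the chord at t_end and leave the weight in flight
        dt = dmove * nloc / C_MM_PER_NS
        if t + dt > t_end:
            dmove = (t_end - t) * C_MM_PER_NS / nloc
            px += dmove * ux
            py += dmove * uy
            pz += dmove * uz
            if lab == 1:
                pp1 += dmove
            elif lab == 2:
                pp2 += dmove
            elif lab == 3:
                pp3 += dmove
            if accumulate and lab > 0:
                path_acc[ix, iy, iz] += acc_w * dmove
            t = t_end
            status = STATUS_TIME_EXPIRED
            out[OUT_RESIDUAL] += w
            break

        px += dmove * ux
        py += dmove * uy
        pz += dmove * uz
        t += dt
        if lab == 1:
            pp1 += dmove
        elif lab == 2:
            pp2 += dmove
        elif lab == 3:
            pp3 += dmove
        if accumulate and lab > 0:
            path_acc[ix, iy, iz] += acc_w * dmove

        if interact:
            # implicit capture: deposit the absorbed share, survive scattering
            dep = w * mua[lab] / mt
            out[OUT_ABSORBED] += dep
            if deposit_fluence:
                fluence[ix, iy, iz] += dep
            w -= dep
            if lab == 1:
                ns1 += 1.0
            elif lab == 2:
                ns2 += 1.0
            elif lab == 3:
                ns3 += 1.0
            if accumulate and lab > 0:
                nsc_acc[ix, iy, iz] += acc_w

            state, u1 = _u01(state)
            state, u2 = _u01(state)
            ct = _hg_cos_theta(g_arr[lab], u1)
            ux, uy, uz = _scatter_direction(ux, uy, uz, ct, 2.0 * math.pi * u2)

            if w < roulette_thr:
                state, u3 = _u01(state)
                if u3 < roulette_p:
                    gain = w * (1.0 / roulette_p - 1.0)
                    out[OUT_ABSORBED] -= gain  # unbiased roulette boost
                    w /= roulette_p
                else:
                    out[OUT_ABSORBED] += w
                    status = STATUS_ABSORBED
                    break
            state, u = _u01(state)
            tau = -math.log(u)
            continue

        # --- face crossing ---
        tau -= dbound * mt
        if tau < 0.0:
            tau = 0.0
        if axis == 0:
            step = 1 if ux > 0.0 else -1
            px = ox + (ix + (1 if step > 0 else 0)) * pitch
            jx, jy, jz = ix + step, iy, iz
        elif axis == 1:
            step = 1 if uy > 0.0 else -1
            py = oy + (iy + (1 if step > 0 else 0)) * pitch
            jx, jy, jz = ix, iy + step, iz
        else:
            step = 1 if uz > 0.0 else -1
            pz = oz + (iz + (1 if step > 0 else 0)) * pitch
            jx, jy, jz = ix, iy, iz + step

        if jx < 0 or jy < 0 or jz < 0 or jx >= nx or jy >= ny or jz >= nz:
            out[OUT_ESCAPED] += w
            status = STATUS_ESCAPED
            break

        lab2 = labels[jx, jy, jz]
        crossed = True
        if wsr and nref[lab2] != nref[lab]:
            if axis == 0:
                ci = abs(ux)
            elif axis == 1:
                ci = abs(uy)
            else:
                ci = abs(uz)
            refl = _fresnel_reflectance(nref[lab], nref[lab2], ci)
            state, u = _u01(state)
            if u < refl:
                # internal reflection: flip the normal component, stay put
                if axis == 0:
                    ux = -ux
                elif axis == 1:
                    uy = -uy
                else:
                    uz = -uz
                crossed = False
            else:
                # Snell refraction at the axis-aligned face normal
                ratio = nref[lab] / nref[lab2]
                sin_t2 = ratio * ratio * (1.0 - ci * ci)
                ct2 = math.sqrt(1.0 - sin_t2)
                if axis == 0:
                    sgn = 1.0 if ux > 0.0 else -1.0
                    uy *= ratio
                    uz *= ratio
                    ux = sgn * ct2
                elif axis == 1:
                    sgn = 1.0 if uy > 0.0 else -1.0
                    ux *= ratio
                    uz *= ratio
                    uy = sgn * ct2
                else:
                    sgn = 1.0 if uz > 0.0 else -1.0
                    ux *= ratio
                    uy *= ratio
                    uz = sgn * ct2
                norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                ux /= norm
                uy /= norm
                uz /= norm

        if crossed:
            # detection: packet transmits out of tissue onto a detector disc
            if lab > 0 and lab2 == 0:
                face = px if axis == 0 else (py if axis == 1 else pz)
                for d in range(det_axis.shape[0]):
                    if det_axis[d] != axis:
                        continue
                    if abs(face - det_plane[d]) > 0.5 * pitch:
                        continue
                    if axis == 0:
                        l1, l2 = py, pz
                    elif axis == 1:
                        l1, l2 = px, pz
                    else:
                        l1, l2 = px, py
                    dd = (l1 - det_c1[d]) ** 2 + (l2 - det_c2[d]) ** 2
                    if dd <= det_r2[d]:
                        det_id = float(d)
                        break
                if det_id >= 0.0:
                    status = STATUS_DETECTED
                    ix, iy, iz = jx, jy, jz
                    break
            ix, iy, iz = jx, jy, jz

    if status == STATUS_STEP_LIMIT:
        out[OUT_RESIDUAL] += w

    out[OUT_STATUS] = float(status)
    out[OUT_DET] = det_id
    out[OUT_W] = w
    out[OUT_T] = t
    out[OUT_PP] = pp1
    out[OUT_PP + 1] = pp2
    out[OUT_PP + 2] = pp3
    out[OUT_NSC] = ns1
    out[OUT_NSC + 1] = ns2
    out[OUT_NSC + 2] = ns3


@njit(cache=True)
def run_photon_batch(
    seed, j0, j1,
    labels, pitch, ox, oy, oz,
    mua, mus, g_arr, nref, ambient_n,
    sx, sy, sz, dx0, dy0, dz0, beam_r, src_axis,
    det_axis, det_plane, det_c1, det_c2, det_r2,
    wsr, t_end, roulette_thr, roulette_p, max_steps,
    fluence,
    rec_j, rec_det, rec_w, rec_t, rec_pp, rec_nsc,
    ledger,
):
    """Launch photons ``j0..j1`` and append detected-packet records.

    ``ledger`` accumulates [launched, absorbed, escaped, detected, residual]
    weight.  Returns the number of records written.
    """
    out = np.empty(OUT_SIZE, dtype=np.float64)
    dummy = np.zeros((1, 1, 1), dtype=np.float64)
    count = 0
    for j in range(j0, j1):
        state = photon_stream_state(seed, j)
        propagate_one(
            state,
            labels, pitch, ox, oy, oz,
            mua, mus, g_arr, nref, ambient_n,
            sx, sy, sz, dx0, dy0, dz0, beam_r, src_axis,
            det_axis, det_plane, det_c1, det_c2, det_r2,
            wsr, t_end, roulette_thr, roulette_p, max_steps,
            fluence, True,
            0.0, dummy, dummy, False,
            out,
        )
        ledger[0] += 1.0
        ledger[1] += out[OUT_ABSORBED]
        ledger[2] += out[OUT_ESCAPED]
        ledger[4] += out[OUT_RESIDUAL]
        if out[OUT_STATUS] == STATUS_DETECTED:
            ledger[3] += out[OUT_W]
            rec_j[count] = j
            rec_det[count] = int(out[OUT_DET])
            rec_w[count] = out[OUT_W]
            rec_t[count] = out[OUT_T]
            for k in range(3):
                rec_pp[count, k] = out[OUT_PP + k]
                rec_nsc[count, k] = out[OUT_NSC + k]
            count += 1
    return count


@njit(cache=True)
def replay_batch(
    seed, rec_j, rec_w, rec_t, rec_pp, rec_gate,
    labels, pitch, ox, oy, oz,
    mua, mus, g_arr, nref, ambient_n,
    sx, sy, sz, dx0, dy0, dz0, beam_r, src_axis,
    det_axis, det_plane, det_c1, det_c2, det_r2,
    wsr, t_end, roulette_thr, roulette_p, max_steps,
    path_acc, nsc_acc, tol,
):
    """Re-propagate recorded packets, accumulating weighted voxel statistics.

    ``path_acc``/``nsc_acc`` are (n_gates, nx, ny, nz); a record's statistics
    land in its exit-time gate slab (a single slab means "all gates").
    Returns -1 on success or the index of the first record whose replayed
    exit weight, time, or per-tissue pathlengths deviate beyond ``tol``.
    """
    out = np.empty(OUT_SIZE, dtype=np.float64)
    dummy = np.zeros((1, 1, 1), dtype=np.float64)
    n_gates = path_acc.shape[0]
    for k in range(rec_j.shape[0]):
        j = rec_j[k]
        gate = rec_gate[k] if n_gates > 1 else 0
        state = photon_stream_state(seed, j)
        propagate_one(
            state,
            labels, pitch, ox, oy, oz,
            mua, mus, g_arr, nref, ambient_n,
            sx, sy, sz, dx0, dy0, dz0, beam_r, src_axis,
            det_axis, det_plane, det_c1, det_c2, det_r2,
            wsr, t_end, roulette_thr, roulette_p, max_steps,
            dummy, False,
            rec_w[k], path_acc[gate], nsc_acc[gate], True,
            out,
        )
        if out[OUT_STATUS] != STATUS_DETECTED:
            return k
        if abs(out[OUT_W] - rec_w[k]) > tol or abs(out[OUT_T] - rec_t[k]) > tol:
            return k
        for c in range(3):
            if abs(out[OUT_PP + c] - rec_pp[k, c]) > tol:
                return k
    return -1
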