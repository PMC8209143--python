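"""Independent straight-line reference implementations used as oracles.

Plain-Python transliterations of the governing equations and rules, written
without reference to the package internals (no numpy vectorization, no
shared helpers), so tests can compare two genuinely separate routes.
"""

from __future__ import annotations

import math

# ---------------------------------------------------------------------------
# plant equations


def ref_dvs(increments, gdd_total):
    acc = 0.0
    for t in increments:
        acc += max(0.0, t)
    return min(acc / gdd_total, 1.0)


def ref_allocation(dvs, storage_w, root_w, leaf_w, stem_w, gamma, m_leaf, m_stem):
    th_storage = dvs * storage_w
    th_root = (1.0 - th_storage) * root_w * gamma / (root_w * gamma + leaf_w + stem_w)
    rem = 1.0 - th_storage - th_root
    s_target = stem_w / (leaf_w + stem_w)
    ag = m_leaf + m_stem
    s_now = m_stem / ag if ag > 0 else s_target
    share = min(max(2.0 * s_target - s_now, 0.0), 1.0)
    th_stem = rem * share
    return th_storage, th_root, rem - th_stem, th_stem


def ref_fp_drought(psi, wilt, fc, h2o):
    if psi <= wilt:
        return 0.0
    return min(1.0, (psi - wilt) / (h2o * (fc - wilt)))


def ref_fp_temp(t, limit):
    v = (t - 0.8 * limit) / (0.2 * limit)
    return min(max(v, 0.0), 1.0)


def ref_fp_nitrogen(c_n_leaf, nc_leaf, exponent):
    return min(1.0, (c_n_leaf / nc_leaf) ** exponent)


def ref_arubisco(rubisco_max, fpd, fpt, fpn):
    return rubisco_max * fpd * fpt * fpn


def ref_gpp(amax, arub, k_ext, lai, par, par_half, co2, co2_half):
    canopy = 1.0 - math.exp(-k_ext * lai)
    light = par / (par + par_half)
    fco2 = (co2 / (co2 + co2_half)) / (400.0 / (400.0 + co2_half))
    return amax * arub * canopy * light * fco2


def ref_rm(mass, coeff, c_to_dm, hourly_t, limit, t_ref):
    total = 0.0
    for t in hourly_t:
        total += ref_fp_temp(t, limit) * 2.0 ** ((t - t_ref) / 10.0)
    return mass * c_to_dm * coeff * total / len(hourly_t)


def ref_fs_drought(psi, wilt, fc, h2o_sen, sen_drought):
    if psi <= wilt:
        return sen_drought
    sat = min(1.0, (psi - wilt) / (h2o_sen * (fc - wilt)))
    return sen_drought * (1.0 - sat)


def ref_fs_frost(t, sen_frost):
    return sen_frost * abs(t) if t < 0.0 else 0.0


def ref_senescence_rate(fs_d, fs_f, fs_a):
    return max(fs_d, fs_f, fs_a)


def ref_n_demand(masses, ncs):
    total = 0.0
    for m, nc in zip(masses, ncs):
        total += m * nc
    return total


def ref_harvest(m_leaf, m_stem, res_leaf, res_stem):
    return max(0.0, m_leaf - res_leaf) + max(0.0, m_stem - res_stem)


def ref_agb_from_elevation(h):
    return 159.0 - 0.058 * h


# ---------------------------------------------------------------------------
# tipping bucket


def ref_bucket(water_mm, fc_mm, infiltration):
    """Cascade infiltration through layers; water above field capacity moves
    to the next layer; bottom excess is deep percolation.  Returns the new
    per-layer water list and the percolation."""
    water = list(water_mm)
    carry = infiltration
    for i in range(len(water)):
        water[i] += carry
        carry = max(0.0, water[i] - fc_mm[i])
        water[i] -= carry
    return water, carry


# ---------------------------------------------------------------------------
# cut scheduler


def ref_schedule(biomass_by_doy, first_cut_latest, max_between, season_end,
                 targets, season_start=1):
    """Day-by-day re-derivation of the cutting rules.

    ``targets(doy, cut_index)`` returns the threshold.  Returns
    ``(doy, trigger)`` pairs.
    """
    events = []
    last_cut = None
    index = 1
    for i, biomass in enumerate(biomass_by_doy):
        doy = i + 1
        if doy < season_start or doy > season_end:
            continue
        cut = None
        if biomass >= targets(doy, index):
            cut = "target_reached"
        elif last_cut is None and index == 1 and doy >= first_cut_latest + 1:
            cut = "doy_fallback"
        elif last_cut is not None and doy - last_cut >= max_between + 1:
            cut = "interval_fallback"
        if cut:
            events.append((doy, cut))
            last_cut = doy
            index += 1
    return events
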