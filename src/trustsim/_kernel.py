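"""Compiled hot path for the interaction loop.

One period is one dyadic interaction.  The kernel advances the population by a
chunk of pre-drawn random numbers and maintains, for every directed
(observer-group, target-group) pair, a sorted copy of the member beliefs so the
distance-weighted group norm can be evaluated in a single O(n) prefix-sum pass
instead of the O(n^2) all-pairs sum.

All state that must survive chunk boundaries (beliefs, sorted arrays, running
sums, checkpoint cursor, intervention flags, convergence record) is passed in
as arrays and mutated in place.
"""
import numpy as np
from numba import njit

# Floor substituted for vanishing distances; keeps weights finite and makes the
# norm continuous in the all-members-agree limit.
EPS_D = 1e-12


@njit(cache=True)
def _sorted_replace(arr, old, new):
    """Replace one occurrence of ``old`` with ``new``, keeping ``arr`` sorted."""
    m = arr.shape[0]
    i = np.searchsorted(arr, old)
    if new >= old:
        j = i
        while j + 1 < m and arr[j + 1] < new:
            arr[j] = arr[j + 1]
            j += 1
        arr[j] = new
    else:
        j = i
        while j - 1 >= 0 and arr[j - 1] > new:
            arr[j] = arr[j - 1]
            j -= 1
        arr[j] = new


@njit(cache=True)
def _norm_sorted(arr, variant):
    """Distance-weighted group norm of a sorted belief vector.

    variant 0: weights 1/d_i with d_i the total absolute distance from all
               members (evaluated via sorted prefix sums);
    variant 1: weights 1/(|b_i - mean| + eps);
    variant 2: weights 1/(|b_i - median| + eps).
    """
    m = arr.shape[0]
    if m == 1:
        return arr[0]
    if arr[0] == arr[m - 1]:
        return arr[0]
    total = 0.0
    for k in range(m):
        total += arr[k]
    num = 0.0
    den = 0.0
    if variant == 0:
        prefix = 0.0
        for k in range(m):
            b = arr[k]
            prefix += b
            d = (2.0 * (k + 1) - m) * b - 2.0 * prefix + total
            if d < EPS_D:
                d = EPS_D
            w = 1.0 / d
            num += w * b
            den += w
    else:
        if variant == 1:
            center = total / m
        else:
            h = m // 2
            if m % 2 == 1:
                center = arr[h]
            else:
                center = 0.5 * (arr[h - 1] + arr[h])
        for k in range(m):
            b = arr[k]
            w = 1.0 / (abs(b - center) + EPS_D)
            num += w * b
            den += w
    return num / den


@njit(cache=True)
def _apply(bel, n_I, s_II, s_IJ, s_JI, s_JJ, sums, track, agent, tgt, new):
    """Commit one belief change, updating sums and sorted arrays."""
    old = bel[agent, tgt]
    if new == old:
        return
    bel[agent, tgt] = new
    if agent < n_I:
        if tgt == 1:
            sums[0] += new - old
            if track:
                _sorted_replace(s_IJ, old, new)
        else:
            if track:
                _sorted_replace(s_II, old, new)
    else:
        if tgt == 0:
            sums[1] += new - old
            if track:
                _sorted_replace(s_JI, old, new)
        else:
            if track:
                _sorted_replace(s_JJ, old, new)


@njit(cache=True)
def _impose_baselines(bel, n_I, baselines, s_II, s_IJ, sums, track):
    """Overwrite every dominant agent with its enlightened baseline value."""
    s0 = 0.0
    for i in range(n_I):
        v = baselines[i]
        bel[i, 0] = v
        bel[i, 1] = v
        s0 += v
    sums[0] = s0
    if track:
        tmp = np.sort(baselines)
        for i in range(n_I):
            s_II[i] = tmp[i]
            s_IJ[i] = tmp[i]


@njit(cache=True)
def _audit(bel, n_I, s_II, s_IJ, s_JI, s_JJ, sums):
    """From-scratch consistency check of the incremental norm state."""
    n = bel.shape[0]
    ref_II = np.sort(bel[:n_I, 0].copy())
    ref_IJ = np.sort(bel[:n_I, 1].copy())
    ref_JI = np.sort(bel[n_I:, 0].copy())
    ref_JJ = np.sort(bel[n_I:, 1].copy())
    for i in range(n_I):
        if s_II[i] != ref_II[i] or s_IJ[i] != ref_IJ[i]:
            return False
    for j in range(n - n_I):
        if s_JI[j] != ref_JI[j] or s_JJ[j] != ref_JJ[j]:
            return False
    if abs(sums[0] - ref_IJ.sum()) > 1e-6 or abs(sums[1] - ref_JI.sum()) > 1e-6:
        return False
    return True


@njit(cache=True)
def record_checkpoint(bel, n_I, s_IJ, s_JI, alpha_mode, alpha_const, norm_variant, out_row):
    """Group means and mean learning rates, with the loop-order summation used
    everywhere in the kernel (so t=0 rows match later checkpoints bit-for-bit)."""
    n = bel.shape[0]
    n_J = n - n_I
    m0 = 0.0
    for i in range(n_I):
        m0 += bel[i, 1]
    m1 = 0.0
    for j in range(n_I, n):
        m1 += bel[j, 0]
    out_row[0] = m0 / n_I
    out_row[1] = m1 / n_J
    if alpha_mode == 0:
        out_row[2] = alpha_const
        out_row[3] = alpha_const
    else:
        norm_I = _norm_sorted(s_IJ, norm_variant)
        norm_J = _norm_sorted(s_JI, norm_variant)
        acc = 0.0
        for i in range(n_I):
            acc += abs(bel[i, 1] - norm_I)
        out_row[2] = acc / n_I
        acc = 0.0
        for j in range(n_I, n):
            acc += abs(bel[j, 0] - norm_J)
        out_row[3] = acc / n_J
    return m0, m1


@njit(cache=True)
def simulate_chunk(
    bel,            # (n, 2) float64, bel[agent, target_group]; mutated
    n_I,            # int: dominant group size, agents [0, n_I)
    s_II, s_IJ, s_JI, s_JJ,   # sorted member-belief copies per directed pair
    sums,           # (2,) [sum bel[I->J], sum bel[J->I]]
    frozen,         # (n,) uint8: 1 = agent never updates its beliefs
    dyad_a, dyad_b,  # (K,) int64 participant indices, a != b
    u_dom, u_sub,   # (K, 2) float64 action uniforms per group stream
    alpha_mode,     # 0 constant, 1 conformity
    alpha_const,
    norm_variant,   # 0 inverse pairwise, 1 mean, 2 median
    action_rule,    # 0 Bernoulli, 1 threshold at 0.5
    t_start,        # interactions completed before this chunk
    ckpt_times,     # (nc,) int64 strictly increasing, all >= 1
    traj,           # (nc, 4) [mean I->J, mean J->I, mean alpha I, mean alpha J]
    ck_state,       # (1,) int64 next checkpoint index
    interv_mode,    # 0 none, 1 instant enlightenment, 2 gradual replacement
    T_e,            # enlightenment time
    baseline_mode,  # 0 frozen, 1 redraw each period
    baselines,      # (n_I,) enlightened baseline values (scratch in redraw mode)
    redraw_vals,    # (n_active, n_I) fresh baselines per active period (redraw)
    redraw_state,   # (1,) int64 row cursor
    repl_interval,
    repl_agents, repl_values,  # gradual replacement draws
    repl_state,     # (1,) int64 event cursor
    repl_learns,    # 0/1
    conv_threshold,
    conv_state,     # (3,) float64 [converged flag, time, common value]
    enl_state,      # (1,) int64 instant-enlightenment active flag
    audit_interval,
):
    n = bel.shape[0]
    n_J = n - n_I
    K = dyad_a.shape[0]
    nc = ckpt_times.shape[0]
    ck = ck_state[0]
    track = alpha_mode == 1

    for si in range(K):
        t = t_start + si + 1
        a = dyad_a[si]
        b = dyad_b[si]
        ga = 0 if a < n_I else 1
        gb = 0 if b < n_I else 1
        ba = bel[a, gb]
        bb = bel[b, ga]
        # Both participants act simultaneously from pre-interaction beliefs.
        ua = u_dom[si, 0] if ga == 0 else u_sub[si, 0]
        ub = u_dom[si, 1] if gb == 0 else u_sub[si, 1]
        if action_rule == 0:
            sa = 1.0 if ua < ba else 0.0
            sb = 1.0 if ub < bb else 0.0
        else:
            sa = 1.0 if ba >= 0.5 else 0.0
            sb = 1.0 if bb >= 0.5 else 0.0
        # Learning rates from the pre-interaction belief configuration.
        if alpha_mode == 0:
            al_a = alpha_const
            al_b = alpha_const
        else:
            if ga == 0:
                arr_a = s_II if gb == 0 else s_IJ
            else:
                arr_a = s_JI if gb == 0 else s_JJ
            if gb == 0:
                arr_b = s_II if ga == 0 else s_IJ
            else:
                arr_b = s_JI if ga == 0 else s_JJ
            al_a = abs(ba - _norm_sorted(arr_a, norm_variant))
            al_b = abs(bb - _norm_sorted(arr_b, norm_variant))
        new_a = al_a * sb + (1.0 - al_a) * ba
        new_b = al_b * sa + (1.0 - al_b) * bb

        enl_now = interv_mode == 1 and t >= T_e
        skip_a = frozen[a] == 1 or (enl_now and enl_state[0] == 1 and ga == 0)
        skip_b = frozen[b] == 1 or (enl_now and enl_state[0] == 1 and gb == 0)
        if not skip_a:
            _apply(bel, n_I, s_II, s_IJ, s_JI, s_JJ, sums, track, a, gb, new_a)
        if not skip_b:
            _apply(bel, n_I, s_II, s_IJ, s_JI, s_JJ, sums, track, b, ga, new_b)

        # Interventions are applied after the learning step of each period.
        if enl_now:
            if enl_state[0] == 0:
                if baseline_mode == 1:
                    r = redraw_state[0]
                    for i in range(n_I):
                        baselines[i] = redraw_vals[r, i]
                    redraw_state[0] = r + 1
                _impose_baselines(bel, n_I, baselines, s_II, s_IJ, sums, track)
                enl_state[0] = 1
            elif baseline_mode == 1:
                r = redraw_state[0]
                for i in range(n_I):
                    baselines[i] = redraw_vals[r, i]
                redraw_state[0] = r + 1
                _impose_baselines(bel, n_I, baselines, s_II, s_IJ, sums, track)
        elif interv_mode == 2 and t >= T_e and t % repl_interval == 0:
            p = repl_state[0]
            agent = repl_agents[p]
            v = repl_values[p]
            repl_state[0] = p + 1
            frozen[agent] = 0
            _apply(bel, n_I, s_II, s_IJ, s_JI, s_JJ, sums, track, agent, 0, v)
            _apply(bel, n_I, s_II, s_IJ, s_JI, s_JJ, sums, track, agent, 1, v)
            if repl_learns == 0:
                frozen[agent] = 1

        # Exact first-passage convergence detection on the group-mean gap.
        if conv_state[0] == 0.0:
            gap = sums[0] / n_I - sums[1] / n_J
            if -conv_threshold < gap < conv_threshold:
                conv_state[0] = 1.0
                conv_state[1] = t
                conv_state[2] = 0.5 * (sums[0] / n_I + sums[1] / n_J)

        if audit_interval > 0 and track and t % audit_interval == 0:
            if not _audit(bel, n_I, s_II, s_IJ, s_JI, s_JJ, sums):
                ck_state[0] = ck
                return 1

        if ck < nc and ckpt_times[ck] == t:
            # Refresh the running sums at checkpoints to cancel float drift.
            m0, m1 = record_checkpoint(
                bel, n_I, s_IJ, s_JI, alpha_mode, alpha_const, norm_variant, traj[ck]
            )
            sums[0] = m0
            sums[1] = m1
            ck += 1

    ck_state[0] = ck
    return 0
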