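"""Compiled fast path of the simulation engine (numba).

Implements exactly the schedule and transition rules of
:mod:`msabm.engine` / :mod:`msabm.dynamics` — pulse trains, shuffled agent
turns (activation, myelin attack + duplication, suppression + duplication,
movement), myelin recovery, aging — on flat numpy state arrays with
per-patch doubly-linked agent buckets, so full-scale cohort runs execute
at compiled speed.  One Mersenne-Twister stream seeded once per run drives
every decision, so runs are bit-reproducible from (params, seed).

The pure-Python engine remains the transparent reference implementation;
the test suite checks the two against each other statistically.  Use
``run_simulation(..., engine="reference")`` to force the Python path.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .geometry import ring_offsets
from .params import Params

# class codes (match the ordering of world.CLASS_KEYS)
TEFF_RESTING, TEFF_ACTIVE, TREG_RESTING, TREG_ACTIVE, VIRUS = 0, 1, 2, 3, 4
DEAD = -1


def _build_tables(n: int, radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Flattened per-patch neighborhood table for one radius.

    Returns (ring_idx, ring_start): ring_idx[q] lists the patches within
    `radius` of q ordered by distance; ring_start gives the boundaries of
    the equal-distance groups (shared by all patches).
    """
    offsets = ring_offsets(n, radius)
    sizes = [len(group) for _, group in offsets]
    ring_start = np.zeros(len(sizes) + 1, dtype=np.int64)
    ring_start[1:] = np.cumsum(sizes)
    total = int(ring_start[-1])
    ring_idx = np.empty((n * n, total), dtype=np.int64)
    col = 0
    for _, group in offsets:
        for di, dj in group:
            base = np.arange(n * n)
            i, j = base // n, base % n
            ring_idx[:, col] = ((i + di) % n) * n + (j + dj) % n
            col += 1
    return ring_idx, ring_start


def _nbr4_table(n: int) -> np.ndarray:
    base = np.arange(n * n)
    i, j = base // n, base % n
    out = np.empty((n * n, 4), dtype=np.int64)
    out[:, 0] = ((i - 1) % n) * n + j
    out[:, 1] = ((i + 1) % n) * n + j
    out[:, 2] = i * n + (j - 1) % n
    out[:, 3] = i * n + (j + 1) % n
    return out


@njit(cache=True, inline="always")
def _list_remove(i, cls_arr, posf, head, prev_, next_, cnt, tot):
    """Unlink agent i from its (class, patch) bucket."""
    b = cls_arr[i] * tot.shape[0] + posf[i]
    p, nx = prev_[i], next_[i]
    if p == -1:
        head[b] = nx
    else:
        next_[p] = nx
    if nx != -1:
        prev_[nx] = p
    cnt[b] -= 1
    tot[posf[i]] -= 1


@njit(cache=True, inline="always")
def _list_insert(i, c, q, cls_arr, posf, head, prev_, next_, cnt, tot):
    """Link agent i of class c into patch q's bucket."""
    b = c * tot.shape[0] + q
    h = head[b]
    next_[i] = h
    prev_[i] = -1
    if h != -1:
        prev_[h] = i
    head[b] = i
    cls_arr[i] = c
    posf[i] = q
    cnt[b] += 1
    tot[q] += 1


@njit(cache=True)
def _run(
    steps,
    seed,
    # lattice + tables
    mye,
    nbr4,
    ring_treg,
    rs_treg,
    ring_virus,
    rs_virus,
    # parameters
    init_mye,
    eat_mye,
    rec_mye,
    eff_dup,
    p_t,
    mean_tregs,
    patch_density,
    hlife,
    pulse_prob,
    virus_pulse_prob,
    per_day,
    steps_per_day,
    agents_per_pulse,
    # output (steps+1 rows)
    out_counts,  # int64[steps+1, 5]
    out_damage,  # float64[steps+1, 3]
):
    np.random.seed(seed)
    n2 = mye.shape[0]
    cap = 4096
    cls_arr = np.full(cap, DEAD, dtype=np.int64)
    life = np.zeros(cap, dtype=np.int64)
    posf = np.zeros(cap, dtype=np.int64)
    prev_ = np.full(cap, -1, dtype=np.int64)
    next_ = np.full(cap, -1, dtype=np.int64)
    head = np.full(5 * n2, -1, dtype=np.int64)
    cnt = np.zeros(5 * n2, dtype=np.int64)
    tot = np.zeros(n2, dtype=np.int64)
    class_totals = np.zeros(5, dtype=np.int64)
    free = np.empty(cap, dtype=np.int64)
    for k in range(cap):
        free[k] = cap - 1 - k
    free_top = cap  # free[:free_top] are available slots
    n_slots = 0  # high-water mark of ever-used slots

    order = np.empty(cap, dtype=np.int64)
    dup_scale = eff_dup / (init_mye * init_mye)

    # record initial state
    for c in range(5):
        out_counts[0, c] = 0
    out_damage[0, 0] = 0.0
    out_damage[0, 1] = 0.0
    out_damage[0, 2] = 0.0

    for t in range(steps):
        # -- grow arrays when a full turn pass could exhaust the slots ---
        live = (
            class_totals[0]
            + class_totals[1]
            + class_totals[2]
            + class_totals[3]
            + class_totals[4]
        )
        if free_top < live + 3 * agents_per_pulse + 8:
            new_cap = cap * 2
            cls2 = np.full(new_cap, DEAD, dtype=np.int64)
            cls2[:cap] = cls_arr
            life2 = np.zeros(new_cap, dtype=np.int64)
            life2[:cap] = life
            posf2 = np.zeros(new_cap, dtype=np.int64)
            posf2[:cap] = posf
            prev2 = np.full(new_cap, -1, dtype=np.int64)
            prev2[:cap] = prev_
            next2 = np.full(new_cap, -1, dtype=np.int64)
            next2[:cap] = next_
            free2 = np.empty(new_cap, dtype=np.int64)
            free2[:cap] = free
            for k in range(new_cap - 1, cap - 1, -1):
                free2[free_top] = k
                free_top += 1
            order2 = np.empty(new_cap, dtype=np.int64)
            cls_arr, life, posf, prev_, next_, free, order = (
                cls2,
                life2,
                posf2,
                prev2,
                next2,
                free2,
                order2,
            )
            cap = new_cap

        # -- 1. pulse trains --------------------------------------------
        if not per_day or t % steps_per_day == 0:
            for species in range(3):  # 0: Teff, 1: Treg, 2: Virus
                if species == 2:
                    p = virus_pulse_prob
                    c = VIRUS
                elif species == 0:
                    p = pulse_prob
                    c = TEFF_RESTING
                else:
                    p = pulse_prob
                    c = TREG_RESTING
                if p > 0.0 and np.random.random() < p:
                    for _ in range(agents_per_pulse):
                        q = np.random.randint(0, n2)
                        free_top -= 1
                        i = free[free_top]
                        if i + 1 > n_slots:
                            n_slots = i + 1
                        life[i] = 1 + np.random.randint(0, 2 * hlife)
                        _list_insert(
                            i, c, q, cls_arr, posf, head, prev_, next_, cnt, tot
                        )
                        class_totals[c] += 1

        # -- 2. shuffled agent turns ------------------------------------
        n_order = 0
        for i in range(n_slots):
            if cls_arr[i] != DEAD:
                order[n_order] = i
                n_order += 1
        # Fisher-Yates
        for k in range(n_order - 1, 0, -1):
            r = np.random.randint(0, k + 1)
            tmp = order[k]
            order[k] = order[r]
            order[r] = tmp

        for k in range(n_order):
            i = order[k]
            c = cls_arr[i]
            if c == DEAD:
                continue  # suppressed or consumed earlier this pass
            q = posf[i]

            if c == TEFF_ACTIVE:
                # myelin attack + duplication attempt
                m = mye[q]
                if m > 0.0:
                    m -= eat_mye
                    if m < 0.0:
                        m = 0.0
                    mye[q] = m
                    for retry in range(2):
                        u = np.random.random()
                        bound = dup_scale * m * m
                        if u >= bound:
                            break
                        # count active Tregs within treg_radius
                        treg_here = 0
                        row = ring_treg[q]
                        for col in range(row.shape[0]):
                            treg_here += cnt[TREG_ACTIVE * n2 + row[col]]
                        if u >= bound * mean_tregs / (treg_here + mean_tregs):
                            break
                        if tot[q] < patch_density:
                            child_q = nbr4[q, np.random.randint(0, 4)]
                            free_top -= 1
                            ci = free[free_top]
                            if ci + 1 > n_slots:
                                n_slots = ci + 1
                            life[ci] = 1 + np.random.randint(0, 2 * hlife)
                            _list_insert(
                                ci,
                                TEFF_ACTIVE,
                                child_q,
                                cls_arr,
                                posf,
                                head,
                                prev_,
                                next_,
                                cnt,
                                tot,
                            )
                            class_totals[TEFF_ACTIVE] += 1
                            half = life[i] // 2
                            life[i] = half if half > 0 else 1
                            break
                        if retry == 1:
                            break
                        # crowded: relocate once and retry with fresh p_e
                        newq = nbr4[q, np.random.randint(0, 4)]
                        _list_remove(
                            i, cls_arr, posf, head, prev_, next_, cnt, tot
                        )
                        _list_insert(
                            i,
                            TEFF_ACTIVE,
                            newq,
                            cls_arr,
                            posf,
                            head,
                            prev_,
                            next_,
                            cnt,
                            tot,
                        )
                        q = newq
                        m = mye[q]

            elif c == TREG_ACTIVE:
                # hunt the nearest active Teff within treg_radius
                if class_totals[TEFF_ACTIVE] > 0:
                    row = ring_treg[q]
                    prey = -1
                    for g in range(rs_treg.shape[0] - 1):
                        total_here = 0
                        for col in range(rs_treg[g], rs_treg[g + 1]):
                            total_here += cnt[TEFF_ACTIVE * n2 + row[col]]
                        if total_here > 0:
                            r = np.random.randint(0, total_here)
                            for col in range(rs_treg[g], rs_treg[g + 1]):
                                qq = row[col]
                                k2 = cnt[TEFF_ACTIVE * n2 + qq]
                                if r < k2:
                                    prey = head[TEFF_ACTIVE * n2 + qq]
                                    while r > 0:
                                        prey = next_[prey]
                                        r -= 1
                                    break
                                r -= k2
                            break
                    if prey != -1:
                        prey_q = posf[prey]
                        _list_remove(
                            prey, cls_arr, posf, head, prev_, next_, cnt, tot
                        )
                        cls_arr[prey] = DEAD
                        class_totals[TEFF_ACTIVE] -= 1
                        free[free_top] = prey
                        free_top += 1
                        # move onto the prey's patch, then try to duplicate
                        _list_remove(
                            i, cls_arr, posf, head, prev_, next_, cnt, tot
                        )
                        _list_insert(
                            i,
                            TREG_ACTIVE,
                            prey_q,
                            cls_arr,
                            posf,
                            head,
                            prev_,
                            next_,
                            cnt,
                            tot,
                        )
                        q = prey_q
                        for retry in range(2):
                            if np.random.random() >= p_t:
                                break
                            if tot[q] < patch_density:
                                child_q = nbr4[q, np.random.randint(0, 4)]
                                free_top -= 1
                                ci = free[free_top]
                                if ci + 1 > n_slots:
                                    n_slots = ci + 1
                                life[ci] = 1 + np.random.randint(0, 2 * hlife)
                                _list_insert(
                                    ci,
                                    TREG_ACTIVE,
                                    child_q,
                                    cls_arr,
                                    posf,
                                    head,
                                    prev_,
                                    next_,
                                    cnt,
                                    tot,
                                )
                                class_totals[TREG_ACTIVE] += 1
                                half = life[i] // 2
                                life[i] = half if half > 0 else 1
                                break
                            if retry == 1:
                                break
                            newq = nbr4[q, np.random.randint(0, 4)]
                            _list_remove(
                                i, cls_arr, posf, head, prev_, next_, cnt, tot
                            )
                            _list_insert(
                                i,
                                TREG_ACTIVE,
                                newq,
                                cls_arr,
                                posf,
                                head,
                                prev_,
                                next_,
                                cnt,
                                tot,
                            )
                            q = newq

            elif c != VIRUS:
                # resting T cell: activate on the nearest virus in radius
                if class_totals[VIRUS] > 0:
                    row = ring_virus[q]
                    target = -1
                    for g in range(rs_virus.shape[0] - 1):
                        total_here = 0
                        for col in range(rs_virus[g], rs_virus[g + 1]):
                            total_here += cnt[VIRUS * n2 + row[col]]
                        if total_here > 0:
                            r = np.random.randint(0, total_here)
                            for col in range(rs_virus[g], rs_virus[g + 1]):
                                qq = row[col]
                                k2 = cnt[VIRUS * n2 + qq]
                                if r < k2:
                                    target = head[VIRUS * n2 + qq]
                                    while r > 0:
                                        target = next_[target]
                                        r -= 1
                                    break
                                r -= k2
                            break
                    if target != -1:
                        _list_remove(
                            target, cls_arr, posf, head, prev_, next_, cnt, tot
                        )
                        cls_arr[target] = DEAD
                        class_totals[VIRUS] -= 1
                        free[free_top] = target
                        free_top += 1
                        # resting -> active, same patch
                        newc = (
                            TEFF_ACTIVE if c == TEFF_RESTING else TREG_ACTIVE
                        )
                        _list_remove(
                            i, cls_arr, posf, head, prev_, next_, cnt, tot
                        )
                        _list_insert(
                            i, newc, q, cls_arr, posf, head, prev_, next_, cnt, tot
                        )
                        class_totals[c] -= 1
                        class_totals[newc] += 1

            # movement: one random Von Neumann step
            c = cls_arr[i]
            newq = nbr4[posf[i], np.random.randint(0, 4)]
            _list_remove(i, cls_arr, posf, head, prev_, next_, cnt, tot)
            _list_insert(i, c, newq, cls_arr, posf, head, prev_, next_, cnt, tot)

        # -- 3. myelin recovery -----------------------------------------
        for q in range(n2):
            m = mye[q]
            if 0.0 < m < init_mye:
                m += rec_mye
                mye[q] = init_mye if m > init_mye else m

        # -- 4. aging and death -----------------------------------------
        for i in range(n_slots):
            if cls_arr[i] == DEAD:
                continue
            life[i] -= 1
            if life[i] <= 0:
                c = cls_arr[i]
                _list_remove(i, cls_arr, posf, head, prev_, next_, cnt, tot)
                cls_arr[i] = DEAD
                class_totals[c] -= 1
                free[free_top] = i
                free_top += 1

        # -- record ------------------------------------------------------
        for c in range(5):
            out_counts[t + 1, c] = class_totals[c]
        rec_dmg = 0.0
        dead_patches = 0
        for q in range(n2):
            m = mye[q]
            if m == 0.0:
                dead_patches += 1
            elif m < init_mye:
                rec_dmg += init_mye - m
        out_damage[t + 1, 0] = rec_dmg
        out_damage[t + 1, 1] = init_mye * dead_patches
        out_damage[t + 1, 2] = rec_dmg + init_mye * dead_patches

    return n_slots


def run_fast(params: Params, seed: int, steps: int):
    """Run the compiled engine; returns (counts, damage, myelin) arrays.

    counts: int64[steps+1, 5] per-class populations per step;
    damage: float64[steps+1, 3] (recoverable, unrecoverable, total);
    myelin: float64[n, n] final lattice state.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    n = params.grid_size
    mye = np.full(n * n, float(params.init_mye))
    nbr4 = _nbr4_table(n)
    ring_treg, rs_treg = _build_tables(n, params.treg_radius)
    ring_virus, rs_virus = _build_tables(n, params.virus_radius)
    out_counts = np.zeros((steps + 1, 5), dtype=np.int64)
    out_damage = np.zeros((steps + 1, 3), dtype=np.float64)
    _run(
        steps,
        seed,
        mye,
        nbr4,
        ring_treg,
        rs_treg,
        ring_virus,
        rs_virus,
        float(params.init_mye),
        float(params.eat_mye),
        float(params.rec_mye),
        float(params.eff_dup),
        float(params.p_t),
        float(params.mean_Tregs),
        int(params.patch_density),
        int(params.hlife),
        float(params.pulse_prob),
        float(params.effective_virus_pulse_prob),
        params.pulse_mode == "per_day",
        int(params.steps_per_day),
        int(params.agents_per_pulse),
        out_counts,
        out_damage,
    )
    return out_counts, out_damage, mye.reshape(n, n)
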