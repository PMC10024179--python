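"""Numba kernels for the agent-based simulation.

All per-step work (secretion, explicit-Euler cytokine diffusion, shuffled
agent updates, delayed recruitment) runs in nopython mode over
structure-of-arrays state.  The Python modules (`cell_rules`, `recruitment`,
`simulation_engine`) are thin wrappers so every rule has exactly one
implementation.

RNG: numba's internal per-thread generator, seeded once per simulation via
:func:`seed_rng`; the engine is single-threaded, so a fixed seed gives a
bit-identical trajectory.
"""

import numpy as np
from numba import njit

# agent kind codes (must match model_core)
EMPTY, CANCER, CTL, DC, MACROPHAGE, HELPER, SUPPRESSOR = 0, 1, 2, 3, 4, 5, 6
N_ANTIGENS = 32

# float-parameter vector layout
FP_PMIG_CANCER = 0
FP_PMIG_IMMUNE = 1
FP_PDEATH = 2
FP_PMUT = 3
FP_PBASE = 4
FP_PBASE_MACRO = 5
FP_TAU_ENH = 6
FP_TAU_SUP = 7
FP_R_ENH = 8
FP_R_CYT = 9
FP_R_CTL = 10
FP_Q_MACRO = 11
FP_Q_SUPP = 12
FP_CHEMO_T = 13
FP_DT_MIN = 14
FP_RECRUIT_SCALE = 15
N_FP = 16

# int-parameter vector layout
IP_TPROLIF = 0
IP_TKILL = 1
IP_TLIFE_CTL = 2
IP_TLIFE_HELPER = 3
IP_TLIFE_SUPP = 4
IP_TLIFE_MACRO = 5
IP_TDELAY = 6
N_IP = 7

# meta (mutable engine bookkeeping) layout
M_FREE_TOP = 0
M_QHEAD = 1
M_KILLS = 2
M_DROPPED = 3
M_BIRTHS = 4
M_DEATHS = 5
M_RECRUITS = 6
M_DEPARTURES = 7
M_RESPAWNS = 8
N_META = 9


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def pkill(p_base, tau_enh, tau_sup, enh, sup, g):
    """CTL/macrophage kill probability.

    (p_base + (1 - p_base) * (1 - exp(-tau_enh*[ENH])) * exp(-tau_sup*[SUP])) ** g
    """
    p = p_base + (1.0 - p_base) * (1.0 - np.exp(-tau_enh * enh)) * np.exp(-tau_sup * sup)
    return p ** g


@njit(cache=True)
def neighbors(p, nx, ny, nz, out):
    """Fill ``out`` with flat indices of the in-bounds Moore neighborhood of
    flat voxel ``p``; returns the neighbor count."""
    x = p % nx
    y = (p // nx) % ny
    z = p // (nx * ny)
    c = 0
    for dz in range(-1, 2):
        zz = z + dz
        if zz < 0 or zz >= nz:
            continue
        for dy in range(-1, 2):
            yy = y + dy
            if yy < 0 or yy >= ny:
                continue
            for dx in range(-1, 2):
                if dx == 0 and dy == 0 and dz == 0:
                    continue
                xx = x + dx
                if xx < 0 or xx >= nx:
                    continue
                out[c] = (zz * ny + yy) * nx + xx
                c += 1
    return c


@njit(cache=True)
def _shuffle(arr, n):
    for i in range(n - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        tmp = arr[i]
        arr[i] = arr[j]
        arr[j] = tmp


@njit(cache=True)
def _remove_agent(i, occ, kind, alive, pos, free_stack, meta):
    occ[pos[i]] = -1
    alive[i] = False
    kind[i] = EMPTY
    free_stack[meta[M_FREE_TOP]] = i
    meta[M_FREE_TOP] += 1


@njit(cache=True)
def _new_slot(free_stack, meta):
    if meta[M_FREE_TOP] <= 0:
        return -1
    meta[M_FREE_TOP] -= 1
    return free_stack[meta[M_FREE_TOP]]


@njit(cache=True)
def _spawn(kind_code, voxel, geno_mask, specificity, step,
           occ, kind, pos, geno, spec, age, immobile, prolif, activated, alive,
           born, free_stack, meta):
    i = _new_slot(free_stack, meta)
    if i < 0:
        return -1
    kind[i] = kind_code
    pos[i] = voxel
    geno[i] = geno_mask
    spec[i] = specificity
    age[i] = 0
    immobile[i] = 0
    prolif[i] = 0
    activated[i] = False
    alive[i] = True
    born[i] = step
    occ[voxel] = i
    return i


@njit(cache=True)
def mutate_mask(mask, p_mutation):
    """Finite-allele mutation: with probability p_mutation toggle one uniform
    allele of the 32; a toggle that would empty the set is redrawn."""
    if np.random.random() >= p_mutation:
        return mask
    while True:
        b = np.random.randint(0, N_ANTIGENS)
        new = mask ^ (1 << b)
        if new != 0:
            return new


@njit(cache=True)
def diffuse(field, D, lam, dt_sub, n_sub, dx, nx, ny, nz, tmp):
    """Explicit (Euler forward) 7-point-Laplacian diffusion with first-order
    decay and zero-flux (Neumann) boundaries, ``n_sub`` substeps in place."""
    k = D / (dx * dx)
    for _ in range(n_sub):
        for z in range(nz):
            for y in range(ny):
                base = (z * ny + y) * nx
                for x in range(nx):
                    p = base + x
                    c = field[p]
                    s = 0.0
                    s += field[p + 1] if x + 1 < nx else c
                    s += field[p - 1] if x - 1 >= 0 else c
                    s += field[p + nx] if y + 1 < ny else c
                    s += field[p - nx] if y - 1 >= 0 else c
                    s += field[p + nx * ny] if z + 1 < nz else c
                    s += field[p - nx * ny] if z - 1 >= 0 else c
                    tmp[p] = c + dt_sub * (k * (s - 6.0 * c) - lam * c)
        field[:] = tmp


@njit(cache=True)
def secrete(occ, kind, pos, activated, alive, enh, sup, fp, n_cap):
    """Deposit one ABM step's secretion at every secreting agent's voxel."""
    dt = fp[FP_DT_MIN]
    r_enh = fp[FP_R_ENH]
    r_cyt = fp[FP_R_CYT]
    for i in range(n_cap):
        if not alive[i]:
            continue
        k = kind[i]
        v = pos[i]
        if k == HELPER:
            enh[v] += r_enh * dt
        elif k == SUPPRESSOR:
            sup[v] += r_enh * dt
        elif k == CTL:
            if activated[i]:
                enh[v] += r_enh * dt
        elif k == MACROPHAGE:
            e = enh[v]
            s = sup[v]
            tot = e + s
            if tot <= 0.0:
                share_e = 0.5
            else:
                share_e = e / tot
            enh[v] += share_e * r_cyt * dt
            sup[v] += (1.0 - share_e) * r_cyt * dt


@njit(cache=True)
def _random_walk(i, p_move, occ, pos, nx, ny, nz, nbuf):
    """Movement with the swap rule; any occupied target swaps w.p. 1/2."""
    if np.random.random() >= p_move:
        return
    n = neighbors(pos[i], nx, ny, nz, nbuf)
    if n == 0:
        return
    t = nbuf[np.random.randint(0, n)]
    j = occ[t]
    if j < 0:
        occ[pos[i]] = -1
        occ[t] = i
        pos[i] = t
    elif np.random.random() < 0.5:
        occ[t] = i
        occ[pos[i]] = j
        pos[j] = pos[i]
        pos[i] = t


@njit(cache=True)
def cancer_step(i, step, occ, debris, kind, pos, geno, spec, age, immobile,
                prolif, activated, alive, born, free_stack, meta,
                fp, ip, nx, ny, nz, nbuf):
    """One step of a cancer cell: death -> debris, mutation, division into a
    vacant Moore neighbor after t_proliferation, then random-walk migration.

    Returns an event code: 0 none/move, 1 died, 2 divided.
    """
    # stochastic death leaves antigen-carrying debris
    if np.random.random() < fp[FP_PDEATH]:
        debris[pos[i]] |= geno[i]
        _remove_agent(i, occ, kind, alive, pos, free_stack, meta)
        meta[M_DEATHS] += 1
        return 1
    # passenger mutation (finite allele, reverse mutations possible)
    geno[i] = mutate_mask(geno[i], fp[FP_PMUT])
    # division attempt
    prolif[i] += 1
    if prolif[i] >= ip[IP_TPROLIF]:
        n = neighbors(pos[i], nx, ny, nz, nbuf)
        n_vac = 0
        for t in range(n):
            if occ[nbuf[t]] < 0:
                nbuf[n_vac] = nbuf[t]
                n_vac += 1
        if n_vac > 0:
            target = nbuf[np.random.randint(0, n_vac)]
            j = _spawn(CANCER, target, geno[i], -1, step,
                       occ, kind, pos, geno, spec, age, immobile, prolif,
                       activated, alive, born, free_stack, meta)
            if j >= 0:
                prolif[i] = 0
                immobile[i] = step + 1  # dividing cells are immobile this step
                meta[M_BIRTHS] += 1
                return 2
        # contact-inhibited: timer stays expired, retry next step
    if immobile[i] > step:
        return 0
    _random_walk(i, fp[FP_PMIG_CANCER], occ, pos, nx, ny, nz, nbuf)
    return 0


@njit(cache=True)
def ctl_step(i, step, occ, debris, kind, pos, geno, spec, age, immobile,
             prolif, activated, alive, born, free_stack, meta,
             enh, sup, fp, ip, g, nx, ny, nz, nbuf, obuf):
    """One step of a CTL: expiry, antigen-specific kill attempt on a Moore
    neighbor (random scan order), else chemotactic/random migration.

    Returns 0 move/idle, 1 expired, 2 engaged (kill attempted), 3 killed.
    """
    if age[i] >= ip[IP_TLIFE_CTL]:
        _remove_agent(i, occ, kind, alive, pos, free_stack, meta)
        meta[M_DEATHS] += 1
        return 1
    if immobile[i] > step:  # still handling a previous kill
        return 0
    # probe neighborhood in random order for a recognizable cancer cell
    n = neighbors(pos[i], nx, ny, nz, nbuf)
    for t in range(n):
        obuf[t] = t
    _shuffle(obuf, n)
    for t in range(n):
        v = nbuf[obuf[t]]
        j = occ[v]
        if j >= 0 and kind[j] == CANCER and (geno[j] >> spec[i]) & 1:
            p = pkill(fp[FP_PBASE], fp[FP_TAU_ENH], fp[FP_TAU_SUP],
                      enh[pos[i]], sup[pos[i]], g)
            if np.random.random() < p:
                debris[pos[j]] |= geno[j]
                _remove_agent(j, occ, kind, alive, pos, free_stack, meta)
                meta[M_KILLS] += 1
                meta[M_DEATHS] += 1
                immobile[i] = step + ip[IP_TKILL]
                return 3
            return 2  # engaged but failed; no move this step
    # migration: chemotaxis up the ENH gradient above threshold, else random walk
    e_local = enh[pos[i]]
    if e_local > fp[FP_CHEMO_T]:
        activated[i] = True
        best = -1.0
        n_best = 0
        for t in range(n):
            v = nbuf[t]
            if occ[v] < 0:
                ev = enh[v]
                if ev > best + 1e-15:
                    best = ev
                    obuf[0] = v
                    n_best = 1
                elif ev > best - 1e-15:
                    obuf[n_best] = v
                    n_best += 1
        if n_best > 0 and best > e_local:
            target = obuf[np.random.randint(0, n_best)]
            occ[pos[i]] = -1
            occ[target] = i
            pos[i] = target
            return 0
        # flat or downhill field: fall through to random walk
    else:
        activated[i] = False
    _random_walk(i, fp[FP_PMIG_IMMUNE], occ, pos, nx, ny, nz, nbuf)
    return 0


@njit(cache=True)
def _random_free_border_voxel(occ, nx, ny, nz, max_tries):
    for _ in range(max_tries):
        axis = np.random.randint(0, 3)
        side = np.random.randint(0, 2)
        if axis == 0:
            x = 0 if side == 0 else nx - 1
            y = np.random.randint(0, ny)
            z = np.random.randint(0, nz)
        elif axis == 1:
            x = np.random.randint(0, nx)
            y = 0 if side == 0 else ny - 1
            z = np.random.randint(0, nz)
        else:
            x = np.random.randint(0, nx)
            y = np.random.randint(0, ny)
            z = 0 if side == 0 else nz - 1
        v = (z * ny + y) * nx + x
        if occ[v] < 0:
            return v
    return -1


@njit(cache=True)
def dc_step(i, step, occ, debris, kind, pos, geno, spec, age, immobile,
            prolif, activated, alive, born, free_stack, meta,
            queues, fp, ip, nx, ny, nz, nbuf):
    """One step of a dendritic cell: collect debris at its voxel; once
    presenting, leave the lattice, push one signal unit per presented antigen
    onto the delay queues, and respawn a naive DC at a free border voxel.

    Returns 0 moved/idle, 1 left (signal pushed).
    """
    if debris[pos[i]] != 0:
        geno[i] |= debris[pos[i]]
        debris[pos[i]] = 0
    if geno[i] != 0:
        newest = (meta[M_QHEAD] + ip[IP_TDELAY] - 1) % ip[IP_TDELAY]
        for b in range(N_ANTIGENS):
            if (geno[i] >> b) & 1:
                queues[newest, b] += 1.0
        _remove_agent(i, occ, kind, alive, pos, free_stack, meta)
        meta[M_DEPARTURES] += 1
        # DC homeostasis: a naive replacement enters at the border
        v = _random_free_border_voxel(occ, nx, ny, nz, 200)
        if v >= 0:
            _spawn(DC, v, 0, -1, step, occ, kind, pos, geno, spec, age,
                   immobile, prolif, activated, alive, born, free_stack, meta)
            meta[M_RESPAWNS] += 1
        else:
            meta[M_DROPPED] += 1
        return 1
    # move to a random vacant neighbor if available
    n = neighbors(pos[i], nx, ny, nz, nbuf)
    n_vac = 0
    for t in range(n):
        if occ[nbuf[t]] < 0:
            nbuf[n_vac] = nbuf[t]
            n_vac += 1
    if n_vac > 0:
        target = nbuf[np.random.randint(0, n_vac)]
        occ[pos[i]] = -1
        occ[target] = i
        pos[i] = target
    return 0


@njit(cache=True)
def accessory_step(i, step, occ, debris, kind, pos, geno, spec, age, immobile,
                   prolif, activated, alive, born, free_stack, meta,
                   enh, sup, fp, ip, g, nx, ny, nz, nbuf, obuf):
    """Helper / suppressor / macrophage step: lifespan expiry, macrophage
    antigen-independent killing, random walk.  Secretion happens in the
    per-step secretion phase.

    Returns 0 move/idle, 1 expired, 2 engaged, 3 killed.
    """
    k = kind[i]
    if k == HELPER:
        life = ip[IP_TLIFE_HELPER]
    elif k == SUPPRESSOR:
        life = ip[IP_TLIFE_SUPP]
    else:
        life = ip[IP_TLIFE_MACRO]
    if age[i] >= life:
        _remove_agent(i, occ, kind, alive, pos, free_stack, meta)
        meta[M_DEATHS] += 1
        return 1
    if immobile[i] > step:
        return 0
    if k == MACROPHAGE:
        # innate cytotoxicity: any adjacent cancer cell, antigen-independent
        n = neighbors(pos[i], nx, ny, nz, nbuf)
        for t in range(n):
            obuf[t] = t
        _shuffle(obuf, n)
        for t in range(n):
            v = nbuf[obuf[t]]
            j = occ[v]
            if j >= 0 and kind[j] == CANCER:
                p = pkill(fp[FP_PBASE_MACRO], fp[FP_TAU_ENH], fp[FP_TAU_SUP],
                          enh[pos[i]], sup[pos[i]], g)
                if np.random.random() < p:
                    debris[pos[j]] |= geno[j]
                    _remove_agent(j, occ, kind, alive, pos, free_stack, meta)
                    meta[M_KILLS] += 1
                    meta[M_DEATHS] += 1
                    immobile[i] = step + ip[IP_TKILL]
                    return 3
                return 2
    _random_walk(i, fp[FP_PMIG_IMMUNE], occ, pos, nx, ny, nz, nbuf)
    return 0


@njit(cache=True)
def advance_queues(queues, meta, tdelay, emitted):
    """Dequeue the oldest per-antigen signal into ``emitted``, enqueue zeros."""
    head = meta[M_QHEAD]
    for b in range(N_ANTIGENS):
        emitted[b] = queues[head, b]
        queues[head, b] = 0.0
    meta[M_QHEAD] = (head + 1) % tdelay


@njit(cache=True)
def _prob_round(x):
    n = int(np.floor(x))
    if np.random.random() < x - n:
        n += 1
    return n


@njit(cache=True)
def spawn_recruits(step, emitted, occ, kind, pos, geno, spec, age, immobile,
                   prolif, activated, alive, born, free_stack, meta,
                   fp, nx, ny, nz):
    """Border recruitment from emitted per-antigen signal.

    CTLs: probabilistic rounding of r_ctl * scale * signal_a per antigen,
    specificity a.  Helpers 1:1 with placed CTLs; macrophages/suppressors at
    q * (placed CTLs), probabilistically rounded.  Recruits that find no free
    border voxel are dropped (counted in meta).
    """
    scale = fp[FP_RECRUIT_SCALE]
    total_ctl = 0
    for a in range(N_ANTIGENS):
        lam = fp[FP_R_CTL] * scale * emitted[a]
        if lam <= 0.0:
            continue
        n = _prob_round(lam)
        for _ in range(n):
            v = _random_free_border_voxel(occ, nx, ny, nz, 200)
            if v < 0:
                meta[M_DROPPED] += 1
                continue
            _spawn(CTL, v, 0, a, step, occ, kind, pos, geno, spec, age,
                   immobile, prolif, activated, alive, born, free_stack, meta)
            total_ctl += 1
    n_helper = total_ctl  # fixed 1:1 ratio
    n_macro = _prob_round(fp[FP_Q_MACRO] * total_ctl)
    n_supp = _prob_round(fp[FP_Q_SUPP] * total_ctl)
    for kcode, count in ((HELPER, n_helper), (MACROPHAGE, n_macro), (SUPPRESSOR, n_supp)):
        for _ in range(count):
            v = _random_free_border_voxel(occ, nx, ny, nz, 200)
            if v < 0:
                meta[M_DROPPED] += 1
                continue
            _spawn(kcode, v, 0, -1, step, occ, kind, pos, geno, spec, age,
                   immobile, prolif, activated, alive, born, free_stack, meta)
    meta[M_RECRUITS] += total_ctl + n_helper + n_macro + n_supp
    return total_ctl


@njit(cache=True)
def sim_step(step, occ, debris, kind, pos, geno, spec, age, immobile, prolif,
             activated, alive, born, free_stack, meta,
             enh, sup, queues, emitted, fp, ip, g,
             d_enh, d_sup, lam_enh, lam_sup, dt_sub, n_sub, dx,
             nx, ny, nz, tmp, nbuf, obuf, ids):
    """One full simulation step.

    Phases: (1) secretion, (2) diffusion substeps, (3) queue advance +
    recruitment, (4) agent updates in uniformly shuffled order.  Returns the
    cancer-cell count after the step.
    """
    cap = kind.shape[0]
    secrete(occ, kind, pos, activated, alive, enh, sup, fp, cap)
    if n_sub > 0:
        diffuse(enh, d_enh, lam_enh, dt_sub, n_sub, dx, nx, ny, nz, tmp)
        diffuse(sup, d_sup, lam_sup, dt_sub, n_sub, dx, nx, ny, nz, tmp)
    advance_queues(queues, meta, ip[IP_TDELAY], emitted)
    spawn_recruits(step, emitted, occ, kind, pos, geno, spec, age, immobile,
                   prolif, activated, alive, born, free_stack, meta,
                   fp, nx, ny, nz)
    # collect live agents (recruits spawned above act from the next step on)
    n_ids = 0
    for i in range(cap):
        if alive[i] and born[i] < step:
            ids[n_ids] = i
            n_ids += 1
    _shuffle(ids, n_ids)
    for t in range(n_ids):
        i = ids[t]
        if not alive[i] or born[i] == step:
            continue
        age[i] += 1
        k = kind[i]
        if k == CANCER:
            cancer_step(i, step, occ, debris, kind, pos, geno, spec, age,
                        immobile, prolif, activated, alive, born, free_stack,
                        meta, fp, ip, nx, ny, nz, nbuf)
        elif k == CTL:
            ctl_step(i, step, occ, debris, kind, pos, geno, spec, age,
                     immobile, prolif, activated, alive, born, free_stack,
                     meta, enh, sup, fp, ip, g, nx, ny, nz, nbuf, obuf)
        elif k == DC:
            dc_step(i, step, occ, debris, kind, pos, geno, spec, age,
                    immobile, prolif, activated, alive, born, free_stack,
                    meta, queues, fp, ip, nx, ny, nz, nbuf)
        else:
            accessory_step(i, step, occ, debris, kind, pos, geno, spec, age,
                           immobile, prolif, activated, alive, born,
                           free_stack, meta, enh, sup, fp, ip, g,
                           nx, ny, nz, nbuf, obuf)
    n_cancer = 0
    for i in range(cap):
        if alive[i] and kind[i] == CANCER:
            n_cancer += 1
    return n_cancer
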