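"""Independent reference implementation of the simulation loop.

Pure-Python single-step dynamics with brute-force O(n^2) norm computation,
consuming random numbers through exactly the same substream protocol as the
production driver (same chunked array draws), so trajectories can be compared
directly: bit-identical in constant-alpha mode, and to tight floating
tolerance in conformity mode (where the production path evaluates the same
norms via sorted prefix sums).
"""
import numpy as np

from trustsim.config import ModelConfig
from trustsim.core_model import CHUNK_SIZE, RngBundle, checkpoint_grid, init_population

EPS_D = 1e-12


def brute_force_distances(beliefs: np.ndarray) -> np.ndarray:
    """d_i = sum_k |b_i - b_k| straight from the definition."""
    return np.abs(beliefs[:, None] - beliefs[None, :]).sum(axis=1)


def brute_force_norm(beliefs: np.ndarray, variant: str) -> float:
    """Group norm from the definition, O(n^2)."""
    m = beliefs.size
    if m == 1 or np.all(beliefs == beliefs[0]):
        return float(beliefs[0])
    if variant == "inverse_pairwise_distance":
        d = np.maximum(brute_force_distances(beliefs), EPS_D)
    else:
        center = np.mean(beliefs) if variant == "distance_from_mean" else np.median(beliefs)
        d = np.abs(beliefs - center) + EPS_D
    w = 1.0 / d
    return float(np.sum(w * beliefs) / np.sum(w))


def run_reference(config: ModelConfig, bundle: RngBundle = None, replication: int = 0):
    """Run one replication step by step; returns (times, traj array, beliefs).

    traj columns: mean I->J, mean J->I, mean alpha I, mean alpha J.
    """
    if bundle is None:
        master = np.random.SeedSequence(config.seed)
        bundle = RngBundle.from_seedseq(master.spawn(config.n_replications)[replication])
    pop = init_population(config, bundle)
    bel = pop.beliefs
    n_I, n = config.n_dominant, config.n_agents
    frozen = np.zeros(n, dtype=bool)

    times = checkpoint_grid(config.horizon, config.checkpoints)
    traj = np.empty((times.size, 4))

    def norm_of(g, t):
        members = bel[:n_I, t] if g == 0 else bel[n_I:, t]
        return brute_force_norm(members, config.norm_variant)

    def record(row):
        m_IJ = bel[:n_I, 1].mean()
        m_JI = bel[n_I:, 0].mean()
        if config.alpha_mode == "constant":
            a_I = a_J = config.alpha_constant
        else:
            a_I = np.mean(np.abs(bel[:n_I, 1] - norm_of(0, 1)))
            a_J = np.mean(np.abs(bel[n_I:, 0] - norm_of(1, 0)))
        traj[row] = (m_IJ, m_JI, a_I, a_J)

    record(0)
    row = 1

    T_e = config.enlightenment_time
    mode = config.intervention_mode
    if mode == "instant_enlightenment" and config.baseline_mode == "frozen":
        baselines = bundle.intervention.random(n_I)
    else:
        baselines = None
    if mode == "gradual_replacement":
        from trustsim.core_model import _gradual_event_count

        n_ev = _gradual_event_count(config.horizon, config.replacement_interval, T_e)
        repl_agents = bundle.intervention.integers(0, n_I, n_ev)
        repl_values = bundle.intervention.random(n_ev)
        repl_ptr = 0
    enlightened = False

    t_done = 0
    while t_done < config.horizon:
        K = int(min(CHUNK_SIZE, config.horizon - t_done))
        dyad_a = bundle.dyad.integers(0, n, K)
        dyad_b = bundle.dyad.integers(0, n - 1, K)
        dyad_b = dyad_b + (dyad_b >= dyad_a)
        u_dom = bundle.action_dominant.random((K, 2))
        u_sub = bundle.action_subordinate.random((K, 2))
        for si in range(K):
            t = t_done + si + 1
            a, b = int(dyad_a[si]), int(dyad_b[si])
            ga = 0 if a < n_I else 1
            gb = 0 if b < n_I else 1
            ba = bel[a, gb]
            bb = bel[b, ga]
            ua = u_dom[si, 0] if ga == 0 else u_sub[si, 0]
            ub = u_dom[si, 1] if gb == 0 else u_sub[si, 1]
            if config.action_rule == "bernoulli":
                sa = 1.0 if ua < ba else 0.0
                sb = 1.0 if ub < bb else 0.0
            else:
                sa = 1.0 if ba >= 0.5 else 0.0
                sb = 1.0 if bb >= 0.5 else 0.0
            if config.alpha_mode == "constant":
                al_a = al_b = config.alpha_constant
            else:
                al_a = abs(ba - norm_of(ga, gb))
                al_b = abs(bb - norm_of(gb, ga))
            new_a = al_a * sb + (1.0 - al_a) * ba
            new_b = al_b * sa + (1.0 - al_b) * bb
            enl_now = mode == "instant_enlightenment" and t >= T_e
            if not (frozen[a] or (enl_now and enlightened and ga == 0)):
                bel[a, gb] = new_a
            if not (frozen[b] or (enl_now and enlightened and gb == 0)):
                bel[b, ga] = new_b
            if enl_now and not enlightened:
                bel[:n_I, 0] = baselines
                bel[:n_I, 1] = baselines
                enlightened = True
            elif mode == "gradual_replacement" and t >= T_e and t % config.replacement_interval == 0:
                agent = int(repl_agents[repl_ptr])
                v = repl_values[repl_ptr]
                repl_ptr += 1
                bel[agent, 0] = v
                bel[agent, 1] = v
                frozen[agent] = not config.replacement_learns
            if row < times.size and times[row] == t:
                record(row)
                row += 1
        t_done += K
    return times, traj, bel
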