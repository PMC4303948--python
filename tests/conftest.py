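import numpy as np
import pytest

from gapcircuit.synth import FixtureSpec, synth_ground_truth


@pytest.fixture(scope="session")
def toy():
    """The default two-gene toy circuit with ground-truth parameters."""
    return synth_ground_truth(FixtureSpec(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_thermo_instance(rng, n_sites=None, n_tfs=4):
    """A random thermodynamic instance for DP-vs-enumeration checks.

    Mixed activators/repressors/neutrals, occasional overlaps,
    cooperativity and quenching on or off.
    """
    from gapcircuit.regions import BindingSite
    from gapcircuit.thermo import ThermoParams

    if n_sites is None:
        n_sites = int(rng.integers(0, 13))
    tfs = [f"tf{j}" for j in range(n_tfs)]
    t_row = {}
    for j, tf in enumerate(tfs):
        kind = rng.integers(0, 3)
        mag = float(rng.uniform(0.5, 50.0))
        t_row[tf] = 0.0 if kind == 0 else (mag if kind == 1 else -mag)
    params = ThermoParams(
        target_gene="g",
        t_row=t_row,
        affinity={tf: float(rng.uniform(1e-3, 0.05)) for tf in tfs},
        cooperativity={tf: float(rng.choice([1.0, 2.0, 5.0]))
                       for tf in tfs},
        repression_range={tf: float(rng.choice([0.0, 30.0, 80.0]))
                          for tf in tfs},
        coop_range=50.0,
        q_btm=float(rng.uniform(0.01, 1.0)),
    )
    sites = []
    pos = 0
    for _ in range(n_sites):
        pos += int(rng.integers(0, 40))
        length = int(rng.integers(6, 11))
        tf = tfs[int(rng.integers(0, n_tfs))]
        sites.append(BindingSite(tf, pos, pos + length, "+",
                                 "A" * length, float(rng.uniform(-3, 0))))
        if rng.random() < 0.7:
            pos += length
        else:
            pos += 1  # next site may overlap this one
    conc = {tf: float(rng.uniform(0.0, 200.0)) for tf in tfs}
    llr_max = {tf: 0.0 for tf in tfs}
    return sites, params, conc, llr_max


def monotone_thermo_instance(rng):
    """Instance with one repressor whose sites cannot interfere.

    Activation is monotone in regulator strengths only when effective
    repressors do not exclude *each other* (repressor-repressor
    interference can free activators and raise E).  Here the single
    repressor's sites are spaced far beyond d_R and the coop range, so
    the quenching of local activators is the only repressive effect.
    """
    from gapcircuit.regions import BindingSite
    from gapcircuit.thermo import ThermoParams

    tfs = ["act1", "act2", "rep"]
    params = ThermoParams(
        target_gene="g",
        t_row={"act1": float(rng.uniform(0.5, 20.0)),
               "act2": float(rng.uniform(0.5, 20.0)),
               "rep": -float(rng.uniform(0.5, 50.0))},
        affinity={tf: float(rng.uniform(1e-3, 0.05)) for tf in tfs},
        cooperativity={tf: float(rng.choice([1.0, 3.0])) for tf in tfs},
        repression_range={tf: 60.0 for tf in tfs},
        coop_range=50.0,
        q_btm=float(rng.uniform(0.01, 0.5)),
    )
    sites = []
    pos = 0
    n_blocks = int(rng.integers(1, 4))
    for _ in range(n_blocks):
        # local cluster: a few activators around at most one repressor
        for _ in range(int(rng.integers(1, 4))):
            sites.append(BindingSite(
                tfs[int(rng.integers(0, 2))], pos, pos + 8, "+",
                "A" * 8, float(rng.uniform(-2, 0))))
            pos += int(rng.integers(10, 40))
        if rng.random() < 0.8:
            sites.append(BindingSite("rep", pos, pos + 8, "+", "A" * 8,
                                     float(rng.uniform(-2, 0))))
        pos += 300    # beyond d_R and coop range: blocks independent
    conc = {tf: float(rng.uniform(1.0, 200.0)) for tf in tfs}
    llr_max = {tf: 0.0 for tf in tfs}
    return sites, params, conc, llr_max
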