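import pytest

import pfasrpf as p


@pytest.fixture(scope="session")
def sim_table():
    """One seeded synthetic summary table at the default study design."""
    return p.simulate_summary_table(p.SimDesign(seed=11))


@pytest.fixture(scope="session")
def parallel_fit(sim_table):
    return p.fit_model(sim_table, p.default_candidates()[2], seed=11)


@pytest.fixture(scope="session")
def recovery_study():
    """Fit 50 seeded replicates of the default design; reused by the
    parameter-recovery and model-selection checks.

    Returns (list of (true_rpfs, est_rpfs) dicts, parallel_win_count).
    """
    candidates = p.default_candidates()
    truths = p.DEFAULT_COMPOUNDS
    index = "PFOA"
    results = []
    wins = 0
    for seed in range(50):
        table = p.simulate_summary_table(p.SimDesign(seed=1000 + seed))
        fits = [p.fit_model(table, spec, seed=seed) for spec in candidates]
        selected = p.select_model(fits)
        if selected.spec.is_parallel:
            wins += 1
        parallel = next(f for f in fits if f.spec.is_parallel)
        est = {c: parallel.params.b[index] / parallel.params.b[c] for c in truths}
        true = {c: truths[index] / truths[c] for c in truths}
        results.append((true, est))
    return results, wins


def small_table():
    """Minimal valid summary table: one compound, control + 3 concentrations,
    two studies."""
    rows = []
    for study in ("1", "2"):
        for conc, mean in ((0.0, 1.0), (2.0, 0.9), (8.0, 0.6), (32.0, 0.3)):
            rows.append(
                p.SummaryRow(compound="PFOA", study=study, concentration=conc,
                             mean=mean, sd=0.05, n=3)
            )
    return p.SummaryTable(endpoint="RAG1", rows=tuple(rows))


@pytest.fixture
def tiny_table():
    return small_table()
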