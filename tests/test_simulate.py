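"""Forward simulator: conservation laws, clock identities, truth labels,
annotation calibration, fixture round trips."""

import filecmp
import os

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from duporigin.epochs import EpochLadder
from duporigin.simulate import (
    AnnotationConfig,
    ClockConfig,
    ConfigError,
    RateConfig,
    SimConfig,
    SimEvent,
    emit_homolog_pairs,
    generate_annotations,
    load_fixture,
    pair_divergence,
    simulate,
    write_fixture,
)

ZERO_RATES = RateConfig(
    loss_base=0, loss_polyploidy=0, loss_single_dup=0,
    relocation_base=0, relocation_burst=0,
    tandem_dup=0, proximal_dup=0, transposed_dup=0,
    burst_window=(10.0, 90.0),
)
SMALL_LADDER = EpochLadder((("O1", 50.0), ("O2", 100.0)))


def zero_config(**kw):
    base = dict(
        n_ancestral_genes=100, n_chromosomes=2, focal="F",
        ladder=SMALL_LADDER, events=(), rates=ZERO_RATES,
        clock=ClockConfig(mu=0.005, sigma=0.0), seed=5,
    )
    base.update(kw)
    return SimConfig(**base)


def test_zero_rate_run_is_exact_identity():
    r = simulate(zero_config())
    for sp in ("F", "O1", "O2"):
        layout = r.genomes[sp]
        assert len(layout) == 100
        sizes = [len(c) for c in layout.chromosomes.values()]
        assert sizes == [50, 50]
    assert (r.truth["truth_origin"] == "singleton").all()
    assert r.event_log.empty


def test_triplication_conserves_and_labels_all_copies():
    """One triplication under zero rates: exactly 300 genes, all wgd-truth,
    none relocated."""
    r = simulate(zero_config(events=(SimEvent(75.0, "triplication"),)))
    assert len(r.genomes["F"]) == 300
    assert len(r.genomes["O1"]) == 300   # split after the event
    assert len(r.genomes["O2"]) == 100   # split before the event
    truth = r.truth
    assert (truth["truth_origin"] == "gamma").all()
    assert (truth["n_relocations"] == 0).all()
    assert truth["expected_mode"].eq("wgd").all()
    # new subgenome chromosomes preserve ancestral order
    fams = [r.families[g] for g in r.genomes["F"].chromosomes["F_c2"]]
    assert fams == sorted(fams)


def test_event_outside_branch_rejected():
    with pytest.raises(ConfigError):
        simulate(zero_config(events=(SimEvent(200.0, "triplication"),)))
    with pytest.raises(ConfigError):
        simulate(zero_config(events=(SimEvent(80.0, "wgd", "O1"),)))  # O1 split at 50
    with pytest.raises(ConfigError):
        SimConfig(rates=RateConfig(burst_window=(100.0, 50.0))).validate()


def test_gene_count_conservation_against_event_log():
    cfg = SimConfig(n_ancestral_genes=300, seed=13)
    r = simulate(cfg)
    log = r.event_log
    for sp, layout in r.genomes.items():
        births = (log[(log["lineage"] == sp) & log["kind"].str.startswith("birth:")]).shape[0]
        deaths = (log[(log["lineage"] == sp) & (log["kind"] == "loss")]).shape[0]
        assert len(layout) - r.lineage_initial[sp] == births - deaths


def test_clock_identity_without_noise():
    cfg = zero_config(events=(SimEvent(75.0, "triplication"),))
    r = simulate(cfg)
    pairs = emit_homolog_pairs(r, "F", top_k=5, ks_cap=10.0)
    # every pair diverged at the triplication: Ks = 2 mu T exactly
    assert np.allclose(pairs["ks"], 2 * 0.005 * 75.0)


def test_pair_divergence_tandem_vs_triplication():
    cfg = SimConfig(
        n_ancestral_genes=60, n_chromosomes=2, focal="F", ladder=SMALL_LADDER,
        events=(SimEvent(75.0, "triplication"),),
        rates=RateConfig(
            loss_base=0, loss_polyploidy=0, loss_single_dup=0,
            relocation_base=0, relocation_burst=0,
            tandem_dup=0.004, proximal_dup=0, transposed_dup=0,
            burst_window=(10.0, 90.0),
        ),
        seed=3,
    )
    r = simulate(cfg)
    truth = r.truth
    tkids = truth[truth["birth_kind"] == "tandem"]
    assert len(tkids) > 0
    reg = r.registry
    for g in tkids["gene"].head(5):
        parent = reg.parent[g]
        if parent in set(truth["gene"]):
            t, kind = pair_divergence(reg, g, parent)
            assert kind == "tandem"
            assert t == reg.btime[g]


def test_top_k_cap_and_ks_cap():
    r = simulate(zero_config(events=(SimEvent(75.0, "triplication"),)))
    assert emit_homolog_pairs(r, "F", top_k=5, ks_cap=0.0).empty
    pairs = emit_homolog_pairs(r, "F", top_k=1, ks_cap=10.0)
    counts = pd.concat([pairs["gene_a"], pairs["gene_b"]]).value_counts()
    # triplicated families have 3 members; top_k=1 keeps at most the
    # symmetric closure of per-gene best pairs
    assert counts.max() <= 2
    with pytest.raises(ValueError):
        emit_homolog_pairs(r, "F", top_k=0)
    with pytest.raises(KeyError):
        emit_homolog_pairs(r, "Nope")


def test_burst_confinement_of_truth_relocations():
    """Every truth relocated-gamma gene's dating relocation lies in the burst
    window and after the triplication."""
    cfg = SimConfig(n_ancestral_genes=400, seed=21)
    r = simulate(cfg)
    lo, hi = cfg.rates.burst_window
    t_gamma = r.gamma_time
    rg = r.truth[r.truth["truth_origin"] == "relocated_gamma"]
    assert len(rg) > 0
    assert ((rg["last_relocation"] >= lo) & (rg["last_relocation"] <= hi)).all()
    assert (rg["last_relocation"] < t_gamma).all()
    assert (rg["birth_time"] >= t_gamma).all()


def test_realized_relocation_fraction_matches_rates(small_sim):
    """Fraction of surviving triplication-born copies with >= 1 relocation
    matches the Poisson expectation from the configured rates."""
    r = small_sim
    cfg = r.config
    t_gamma = r.gamma_time
    lo, hi = cfg.rates.burst_window
    burst_exposure = max(0.0, min(hi, t_gamma) - lo)
    base_exposure = t_gamma - burst_exposure
    p = 1.0 - np.exp(-(cfg.rates.relocation_burst * burst_exposure
                       + cfg.rates.relocation_base * base_exposure))
    born = r.truth[r.truth["birth_kind"] == "triplication"]
    frac = (born["n_relocations"] > 0).mean()
    se = np.sqrt(p * (1 - p) / len(born))
    assert abs(frac - p) < 4 * se


def test_same_seed_byte_identical_fixtures(tmp_path):
    cfg = SimConfig(n_ancestral_genes=120, seed=9)
    for d in ("a", "b"):
        r = simulate(cfg)
        ann = generate_annotations(r, seed=1)
        write_fixture(r, ann, tmp_path / d)
    files = sorted(os.listdir(tmp_path / "a"))
    assert files == sorted(os.listdir(tmp_path / "b"))
    for f in files:
        assert filecmp.cmp(tmp_path / "a" / f, tmp_path / "b" / f, shallow=False), f


def test_fixture_round_trip(tmp_path, small_sim):
    ann = generate_annotations(small_sim, seed=2)
    write_fixture(small_sim, ann, tmp_path)
    fx = load_fixture(tmp_path)
    assert fx.focal == small_sim.config.focal
    for sp, layout in small_sim.genomes.items():
        assert fx.layouts[sp].chromosomes == layout.chromosomes
    pd.testing.assert_frame_equal(
        fx.pairs, emit_homolog_pairs(small_sim, "At"), check_exact=False, rtol=1e-12
    )
    assert fx.ladder == small_sim.config.ladder
    assert set(fx.annotations.pwm_hits) == set(ann.pwm_hits)
    assert all(fx.annotations.pwm_hits[g] == ann.pwm_hits[g] for g in ann.pwm_hits)
    pd.testing.assert_frame_equal(fx.annotations.expression, ann.expression,
                                  check_exact=False, rtol=1e-9, check_names=False)


def test_empty_genome_fixture_headers_only(tmp_path):
    cfg = zero_config(n_ancestral_genes=1)
    r = simulate(cfg)
    write_fixture(r, None, tmp_path)
    fx = load_fixture(tmp_path)
    assert len(fx.layouts["F"]) == 1
    assert fx.pairs.empty


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def test_null_annotation_config_gives_class_independence(small_sim):
    cfg = AnnotationConfig(essential_multipliers={}, ppi_multipliers={}, go_multipliers={})
    ann = generate_annotations(small_sim, cfg, seed=3)
    df = ann.essential.merge(small_sim.truth[["gene", "truth_origin"]], on="gene")
    df = df[df["truth_origin"].isin(["gamma", "tandem", "dispersed_other", "singleton"])]
    table = pd.crosstab(df["truth_origin"], df["essential"])
    _, p, _, _ = stats.chi2_contingency(table)
    assert p > 0.001


def test_essentiality_multiplier_hits_configured_rate(small_sim):
    cfg = AnnotationConfig(essential_base=0.1,
                           essential_multipliers={"relocated_gamma": 3.0})
    ann = generate_annotations(small_sim, cfg, seed=4)
    df = ann.essential.merge(small_sim.truth[["gene", "truth_origin"]], on="gene")
    rg = df[df["truth_origin"] == "relocated_gamma"]["essential"]
    se = np.sqrt(0.3 * 0.7 / len(rg))
    assert abs(rg.mean() - 0.3) < 4 * se
    other = df[df["truth_origin"] == "gamma"]["essential"]
    assert abs(other.mean() - 0.1) < 4 * np.sqrt(0.1 * 0.9 / len(other))


def test_negative_multiplier_rejected(small_sim):
    with pytest.raises(ConfigError):
        generate_annotations(small_sim, AnnotationConfig(essential_multipliers={"gamma": -1}))


def test_age_zero_pairs_have_identical_pwm_sets_and_corr_decay():
    """Motif sets are inherited exactly at age 0; expression correlation and
    motif overlap decay with pair age."""
    cfg = SimConfig(n_ancestral_genes=300, seed=17)
    r = simulate(cfg)
    ann = generate_annotations(r, seed=5)
    reg = r.registry
    truth = r.truth.set_index("gene")
    genes = list(truth.index)
    by_fam = {}
    for g in genes:
        by_fam.setdefault(reg.family[g], []).append(g)
    ages, jacc, corr = [], [], []
    expr = ann.expression
    for fam, fg in by_fam.items():
        for i in range(len(fg)):
            for j in range(i + 1, len(fg)):
                t, _ = pair_divergence(reg, fg[i], fg[j])
                sa, sb = ann.pwm_hits[fg[i]], ann.pwm_hits[fg[j]]
                if not (sa | sb):
                    continue
                ages.append(t)
                jacc.append(len(sa & sb) / len(sa | sb))
                corr.append(np.corrcoef(expr.loc[fg[i]], expr.loc[fg[j]])[0, 1])
    ages = np.array(ages)
    assert (np.array(jacc)[ages < 1.0] > 0.99).all()
    rho_j = stats.spearmanr(ages, jacc).statistic
    rho_c = stats.spearmanr(ages, corr).statistic
    assert rho_j < -0.2 and rho_c < -0.2
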