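"""Synthetic generators: reproducibility, noise calibration, toy oracles."""

import numpy as np
import pytest

from isogly.rate_laws import IsoenzymeKinetics, mm_irreversible
from isogly.synthetic_data import (
    SynthesisSpec,
    make_assay,
    make_omics_tables,
    make_toy_network,
)

ADH1 = IsoenzymeKinetics("Adh1p", "mm_irreversible", kcat=176.0, Km={"ACE": 0.462})


def test_identical_seed_bitwise_identical():
    a = make_assay(ADH1, SynthesisSpec(seed=42))
    b = make_assay(ADH1, SynthesisSpec(seed=42))
    assert a.points == b.points


def test_different_seed_differs():
    a = make_assay(ADH1, SynthesisSpec(seed=1))
    b = make_assay(ADH1, SynthesisSpec(seed=2))
    assert a.points != b.points


def test_zero_noise_reproduces_law_exactly():
    data = make_assay(ADH1, SynthesisSpec(seed=0, noise_cv_percent=0.0),
                      enzyme_conc=2e-3)
    for s, reps in data.points:
        expected = mm_irreversible(2e-3, 176.0, s, 0.462)
        assert all(r == pytest.approx(expected, rel=1e-14) for r in reps)


def test_replicate_mean_converges_to_true_rate():
    spec = SynthesisSpec(seed=9, replicates=1000, noise_cv_percent=5.0,
                         s_grid=(0.05, 0.2, 0.462, 1.0, 5.0))
    data = make_assay(ADH1, spec, enzyme_conc=1e-3)
    for s, reps in data.points:
        true = mm_irreversible(1e-3, 176.0, s, 0.462)
        assert np.mean(reps) == pytest.approx(true, rel=0.01)


def test_noise_magnitude_matches_requested_cv():
    spec = SynthesisSpec(seed=4, replicates=4000, noise_cv_percent=10.0,
                         s_grid=(0.1, 0.5, 1.0, 2.0, 5.0))
    data = make_assay(ADH1, spec)
    s, reps = data.points[2]
    cv = np.std(reps) / np.mean(reps)
    assert cv == pytest.approx(0.10, rel=0.1)


class TestOmicsTables:
    def test_zero_cv_returns_truth(self, tables):
        spec = SynthesisSpec(seed=0)
        noisy = make_omics_tables(tables, spec)
        # rows without a reported SEM are exact; perturbed rows differ
        has_sem = tables.proteins["sem_percent"].notna()
        same = noisy.proteins["copies_per_cell"] == tables.proteins["copies_per_cell"]
        assert same[~has_sem].all()

    def test_absent_isoenzyme_stays_absent(self, tables):
        noisy = make_omics_tables(tables, SynthesisSpec(seed=3))
        tdh2 = noisy.proteins.loc[noisy.proteins["isoenzyme"] == "Tdh2p",
                                  "copies_per_cell"]
        assert float(tdh2.iloc[0]) == 0.0

    def test_perturbation_scale_matches_row_cv(self, tables):
        # Monte-Carlo over seeds: relative spread tracks the SEM column
        import pandas as pd

        row = tables.proteins[tables.proteins["isoenzyme"] == "Pdc5p"]
        true = float(row["copies_per_cell"].iloc[0])
        cv_target = float(row["sem_percent"].iloc[0]) / 100.0
        draws = []
        for seed in range(300):
            noisy = make_omics_tables(tables, SynthesisSpec(seed=seed))
            draws.append(float(
                noisy.proteins.loc[noisy.proteins["isoenzyme"] == "Pdc5p",
                                   "copies_per_cell"].iloc[0]
            ))
        cv = np.std(draws) / np.mean(draws)
        assert cv == pytest.approx(cv_target, rel=0.25)


class TestToyNetworks:
    def test_linear3_steady_state_matches_algebra(self):
        from isogly.simulate import steady_state

        p = {"A": 2.0, "k1": 1.0, "k2": 0.6, "k3": 0.3, "Keq": 2.0}
        m = make_toy_network("linear3", params=p)
        ss = steady_state(m)
        assert ss.converged
        # chain of two reversible steps and a first-order sink, solved by hand
        j = ss.fluxes["R3"]
        c = ss.concentrations
        assert ss.fluxes["R1"] == pytest.approx(j, abs=1e-10)
        assert ss.fluxes["R2"] == pytest.approx(j, abs=1e-10)
        assert p["k1"] * (p["A"] - c["B"] / p["Keq"]) == pytest.approx(j, abs=1e-9)
        assert p["k3"] * c["C"] == pytest.approx(j, abs=1e-10)

    def test_linear2_fccs_sum_to_one(self):
        from isogly.mca import control_profile

        m = make_toy_network("linear2")
        prof = control_profile(m, target="R2")
        assert prof.summation_residual < 1e-6

    def test_branch_template_conserves_adenine_pair(self):
        from isogly.simulate import Dynamics, steady_state

        m = make_toy_network("branch")
        supports = [frozenset(g) for g in Dynamics(m).moieties()]
        assert frozenset({"ATP", "ADP"}) in supports
        ss = steady_state(m)
        assert ss.converged
        assert ss.concentrations["ATP"] + ss.concentrations["ADP"] == pytest.approx(
            2.0, rel=1e-9
        )

    def test_unknown_template_rejected(self):
        with pytest.raises(ValueError):
            make_toy_network("ring")


def test_zero_noise_assay_to_model_pipeline_is_exact():
    """Fit kinetics from noise-free synthetic assays, build a reaction
    from the fitted isoenzymes, and recover the generating rates."""
    from isogly.assay_fitting import fit_michaelis_menten
    from isogly.rate_laws import reaction_rate

    truths = [
        IsoenzymeKinetics("iso1", "mm_irreversible", kcat=20.0, Km={"S": 0.5}),
        IsoenzymeKinetics("iso2", "mm_irreversible", kcat=5.0, Km={"S": 2.0}),
    ]
    fitted = []
    for truth in truths:
        data = make_assay(truth, SynthesisSpec(seed=0, noise_cv_percent=0.0),
                          substrate="S")
        fit = fit_michaelis_menten(data)
        fitted.append(IsoenzymeKinetics(truth.isoenzyme_id, "mm_irreversible",
                                        kcat=fit.kcat, Km={"S": fit.Km}))
    conc = {"S": 1.3}
    pairs_true = [(t, 0.01) for t in truths]
    pairs_fit = [(f, 0.01) for f in fitted]
    assert reaction_rate(pairs_fit, conc) == pytest.approx(
        reaction_rate(pairs_true, conc), rel=1e-8
    )
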