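import numpy as np
import pytest

from dcache_ai2 import (AssayGenConfig, FamilyGenConfig, GradientPlateMeasurement,
                        OneSiteParams, TitrationProtocol, build_column_map,
                        capillary_net_count, classify, classify_all,
                        generate_assay_dataset, generate_family,
                        generate_itc_dataset, response_index, screen_family,
                        simulate_titration)


def test_family_generation_is_deterministic(ref):
    cfg = FamilyGenConfig(n_seqs=50, seed=123)
    a = generate_family(cfg)
    b = generate_family(cfg)
    assert a[0].rows == b[0].rows
    assert a[1] == b[1]
    assert a[2].n_match == b[2].n_match


def test_all_full_match_family_passes_entirely(ref):
    cfg = FamilyGenConfig(n_seqs=10, full_match_fraction=1.0,
                          partial_match_fraction=0.0, seed=1)
    family, _, truth = generate_family(cfg)
    cmap = build_column_map(family, ref)
    res = screen_family(family, cmap, ref, k=5)
    assert res.n_passing == len(family) == 11  # 10 planted + reference row
    assert truth.expected_pass_count(5) == 11


def test_planted_full_match_count_is_exact(ref):
    cfg = FamilyGenConfig(n_seqs=5000, full_match_fraction=0.1,
                          partial_match_fraction=0.0, seed=99)
    family, _, truth = generate_family(cfg)
    assert truth.n_full_planted == 500
    cmap = build_column_map(family, ref)
    res = screen_family(family, cmap, ref, k=5)
    assert res.n_passing == 501  # 500 planted + the reference row


def test_partial_matches_carry_exactly_four(ref):
    cfg = FamilyGenConfig(n_seqs=200, full_match_fraction=0.0,
                          partial_match_fraction=1.0, seed=17)
    family, _, truth = generate_family(cfg)
    counts = [v for k, v in truth.n_match.items() if k != ref.reference_id]
    assert counts == [4] * 200


def test_classify_of_generated_metadata_equals_planted_labels():
    cfg = FamilyGenConfig(n_seqs=300, seed=21)
    _, metadata, truth = generate_family(cfg)
    assert classify_all(metadata) == truth.classes


def test_uncharacterized_distribution_yields_empty_output_domains():
    cfg = FamilyGenConfig(n_seqs=20, class_distribution={"UNCHARACTERIZED": 1.0},
                          seed=2)
    _, metadata, truth = generate_family(cfg)
    for m in metadata:
        if m.accession != "PctA":
            assert m.output_domains == ()
            assert classify(m)[0] == "UNCHARACTERIZED"


def test_indel_columns_do_not_change_screen_results(ref):
    base = FamilyGenConfig(n_seqs=150, full_match_fraction=0.2, seed=5)
    with_indels = FamilyGenConfig(n_seqs=150, full_match_fraction=0.2, seed=5,
                                  indel_rate=0.1)
    fam_a, _, truth_a = generate_family(base)
    fam_b, _, truth_b = generate_family(with_indels)
    assert fam_b.n_columns > fam_a.n_columns
    cmap_b = build_column_map(fam_b, ref)
    res_b = screen_family(fam_b, cmap_b, ref, k=5)
    assert res_b.n_passing == truth_b.expected_pass_count(5)
    assert truth_a.n_full_planted == truth_b.n_full_planted


def test_shuffle_gap_corruption_leaves_retained_columns_invariant(ref):
    cfg = FamilyGenConfig(n_seqs=100, full_match_fraction=0.3, seed=6,
                          indel_rate=0.15, shuffle_gap_columns=True)
    family, _, truth = generate_family(cfg)
    cmap = build_column_map(family, ref)
    res = screen_family(family, cmap, ref, k=5)
    assert res.n_passing == truth.expected_pass_count(5)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        FamilyGenConfig(full_match_fraction=0.8, partial_match_fraction=0.4)
    with pytest.raises(ValueError):
        FamilyGenConfig(class_distribution={"MCP": 0.6})
    with pytest.raises(ValueError):
        FamilyGenConfig(indel_rate=-0.1)


def test_itc_dataset_single_replicate_matches_direct_simulation():
    protocol = TitrationProtocol(syringe_conc_M=700e-6, cell_conc_M=70e-6)
    params = OneSiteParams(Kd=1e-6, q_offset=3.0)
    (signal, control), = generate_itc_dataset(protocol, params, 0.0, 1, seed=4)
    direct = simulate_titration(protocol, params, 0.0)
    assert signal.heats_uJ == direct.heats_uJ
    assert control.heats_uJ == (3.0,) * 25  # dilution = offset only


def test_itc_dataset_reproducible_and_replicates_differ():
    protocol = TitrationProtocol(syringe_conc_M=700e-6, cell_conc_M=70e-6)
    params = OneSiteParams(Kd=1e-6)
    a = generate_itc_dataset(protocol, params, 1.0, 3, seed=10)
    b = generate_itc_dataset(protocol, params, 1.0, 3, seed=10)
    for (sa, ca), (sb, cb) in zip(a, b):
        assert sa.heats_uJ == sb.heats_uJ and ca.heats_uJ == cb.heats_uJ
    assert a[0][0].heats_uJ != a[1][0].heats_uJ


def test_assay_dataset_means_track_configured_effects():
    cfg = AssayGenConfig(n=400)
    plate, capillary = generate_assay_dataset(cfg, seed=8)
    ris = [response_index(GradientPlateMeasurement(r.D1_mm, r.D2_mm))
           for r in plate.itertuples()]
    assert np.mean(ris) == pytest.approx(0.65, abs=0.01)
    nets = [capillary_net_count(r.treatment_cfu, r.buffer_cfu)[0]
            for r in capillary.itertuples()]
    assert np.mean(nets) == pytest.approx(800, rel=0.05)

    symmetric = AssayGenConfig(d1_mean_mm=5.0, d2_mean_mm=5.0, n=400,
                               capillary_treatment_rate=200.0)
    plate_s, capillary_s = generate_assay_dataset(symmetric, seed=9)
    ris_s = [response_index(GradientPlateMeasurement(r.D1_mm, r.D2_mm))
             for r in plate_s.itertuples()]
    assert np.mean(ris_s) == pytest.approx(0.5, abs=0.01)
    nets_s = [capillary_net_count(r.treatment_cfu, r.buffer_cfu)[0]
              for r in capillary_s.itertuples()]
    assert np.mean(nets_s) < 25  # zero-attraction: net counts near zero
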