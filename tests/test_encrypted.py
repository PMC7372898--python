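"""Encrypted pipeline integration tests on the toy profile.

One prepared context is shared across runs (key material depends only on the
cohort shape and conversion method); each test that runs the circuit asserts
against the plaintext semi-parallel reference.
"""

import json

import numpy as np
import pytest

from hegwas.gwas_encrypted import (plan_levels, prepare_context,
                                   run_encrypted, save_manifest)
from hegwas.gwas_plain import fit_covariates, semi_parallel_z
from hegwas.rns import generate_modulus_chain
from hegwas.synthetic import SimConfig, generate

N, M, K = 16, 64, 3


@pytest.fixture(scope="module")
def toy_ds():
    ds, _ = generate(SimConfig(N=N, M=M, K=K, n_causal=3, seed=0))
    return ds


@pytest.fixture(scope="module")
def toy_ctx():
    return prepare_context(N, M, k=K + 1, seed=0, conversion_method=1)


def test_encrypted_matches_plain(toy_ds, toy_ctx):
    run = run_encrypted(toy_ds, context=toy_ctx)
    plain = semi_parallel_z(toy_ds, fit_covariates(toy_ds).theta)
    assert np.max(np.abs(run.result.z - plain.z)) < 5e-4
    assert np.array_equal(run.result.degenerate, plain.degenerate)
    # detH is reported unnormalized
    assert np.isclose(run.result.detH, plain.detH, rtol=1e-3)


def test_counters_reset_between_runs_on_shared_context(toy_ctx):
    snapshots = []
    for seed in (1, 2):
        ds, _ = generate(SimConfig(N=N, M=M, K=K, n_causal=3, seed=seed))
        run = run_encrypted(ds, context=toy_ctx)
        snapshots.append(run.manifest)
    a, b = snapshots
    assert a["snp_phase"] == b["snp_phase"]
    assert a["counters"]["rotations"] == b["counters"]["rotations"]
    assert a["counters"]["native_ntts"] == b["counters"]["native_ntts"]


def test_snp_phase_key_switch_budget(toy_ds, toy_ctx):
    """From the first use of the SNP ciphertexts to the end: k^2 = 16
    relinearizations and zero rotations."""
    run = run_encrypted(toy_ds, context=toy_ctx)
    snp = run.manifest["snp_phase"]
    assert snp == {"relinearizations": 16, "rotations": 0,
                   "key_switches": 16}


def test_conversion_method3_equivalent(toy_ds):
    ctx3 = prepare_context(N, M, k=K + 1, seed=0, conversion_method=3)
    run = run_encrypted(toy_ds, conversion_method=3, context=ctx3)
    plain = semi_parallel_z(toy_ds, fit_covariates(toy_ds).theta)
    assert np.max(np.abs(run.result.z - plain.z)) < 5e-4
    assert run.manifest["snp_phase"]["key_switches"] == 16


def test_method2_on_shallow_chain_raises_depth_error(toy_ds):
    """The binary-tree conversion costs an extra ceil(log2 Nbar) mask
    levels; on the default toy chain it must fail with a clean depth
    error, not a wrong answer."""
    ctx2 = prepare_context(N, M, k=K + 1, seed=0, conversion_method=2)
    with pytest.raises(ValueError, match="depth"):
        run_encrypted(toy_ds, conversion_method=2, context=ctx2)


def test_context_missing_rotation_keys_rejected(toy_ds, toy_ctx):
    with pytest.raises(ValueError, match="rotation keys"):
        run_encrypted(toy_ds, conversion_method=3, context=toy_ctx)


def test_manifest_contents(toy_ds, toy_ctx, tmp_path):
    run = run_encrypted(toy_ds, context=toy_ctx)
    man = run.manifest
    assert man["plan"]["input_levels"] == {"X": 22, "Xt": 22, "y": 22,
                                           "S": 7, "X1": 6}
    assert man["dims"] == {"N": N, "M": M, "k": K + 1}
    sizes = man["sizes_bytes"]
    n = man["chain"]["n"]
    assert sizes["S"] == N * 2 * 7 * n * 8
    assert sizes["X1"] == N * (K + 1) * 2 * 6 * n * 8
    assert sizes["secret_key"] == 2 * 22 * n * 8
    path = str(tmp_path / "manifest.json")
    save_manifest(path, man)
    with open(path) as fh:
        assert json.load(fh)["snp_phase"] == man["snp_phase"]


def test_plan_levels_paper_profile_schedule():
    chain = generate_modulus_chain(30, 32, 17)
    plan = plan_levels(chain, 245, 4, "paper")
    assert plan.input_levels["S"] == 7
    assert plan.input_levels["X1"] == 6
    assert plan.rotation_keys == {17: 16, 12: 13, 9: 12}
    shallow = generate_modulus_chain(30, 32, 5)
    with pytest.raises(ValueError):
        plan_levels(shallow, 245, 4, "paper")
    with pytest.raises(ValueError):
        plan_levels(shallow, 245, 4, "toy")
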