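"""Evaluation report, storage ledger, binary containers and CLI surface."""

import json
from fractions import Fraction

import numpy as np
import pytest
from click.testing import CliRunner

from hegwas import serialize as ser
from hegwas.ckks import (CkksContext, sizeof_ciphertext, sizeof_secret_key,
                         sizeof_switchkey)
from hegwas.cli import main as cli_main
from hegwas.evaluate import confusion_f1, paper_plan, storage_report
from hegwas.rns import generate_modulus_chain

SIG, NUL = 0.001, 0.5  # clearly significant / null p-values


def test_confusion_identical_vectors_f1_one():
    r = confusion_f1([SIG, NUL, SIG], [SIG, NUL, SIG])
    assert r.f1 == 1.0 and r.tp == 2 and r.fp == 0 and r.fn == 0
    assert r.tpr == 1.0 and r.fnr == 0.0
    # the empty case: no positives anywhere is perfect agreement too
    assert confusion_f1([NUL], [NUL]).f1 == 1.0


def test_confusion_all_discordant_f1_zero():
    r = confusion_f1([SIG, SIG, NUL, NUL], [NUL, NUL, SIG, SIG])
    assert r.tp == 0 and r.f1 == 0.0


def test_confusion_hand_contingency():
    ref = [SIG] * 4 + [NUL] * 3
    test = [SIG] * 3 + [NUL] + [SIG] + [NUL] * 2
    r = confusion_f1(ref, test)
    assert (r.tp, r.fp, r.fn, r.tn) == (3, 1, 1, 2)
    assert r.f1 == 0.75


def test_confusion_length_mismatch():
    with pytest.raises(ValueError):
        confusion_f1([SIG], [SIG, NUL])


def test_report_serializes(tmp_path):
    r = confusion_f1([SIG, NUL], [SIG, SIG], counters={"rotations": 3},
                     sizes={"S": 100})
    doc = r.to_dict()
    json.dumps(doc)
    assert doc["counters"]["rotations"] == 3
    assert doc["pairs"] == [[SIG, SIG], [NUL, SIG]]


def test_storage_report_reproduces_table():
    """Full-profile ledger: S 0.84 GiB, X1 2.87 GiB, rotation keys 3.65 GiB,
    secret key 8.5 MiB, ratios 2.4x and 1.3x, under GiB = 2^30."""
    rep = storage_report(paper_plan(), {"N": 245, "M": 10643, "K": 3,
                                        "n": 32768})
    o = rep["objects"]
    assert o["S"]["count"] == 245 and o["S"]["level"] == 7
    assert round(o["S"]["gib"], 2) == 0.84
    assert o["X1"]["count"] == 980
    assert round(o["X1"]["gib"], 2) == 2.87
    assert round(o["rotation_keys"]["gib"], 2) == 3.65
    assert round(o["secret_key"]["mib"], 1) == 8.5
    assert round(rep["ratios"]["S_fresh_over_first_use"], 1) == 2.4
    assert round(
        rep["ratios"]["S_position_counted_over_depth_counted"], 1) == 1.3
    assert rep["depth_increase_naive_rowsum_bits"] == 8


def test_storage_report_toy_hand_arithmetic():
    from hegwas.gwas_encrypted import plan_levels
    chain = generate_modulus_chain(45, 1 << 12, 22)
    plan = plan_levels(chain, 16, 4, "toy", rotation_offsets=[1, 2])
    rep = storage_report(plan, {"N": 16, "M": 64, "K": 3, "n": 1 << 12})
    o = rep["objects"]
    assert o["S"]["bytes"] == 16 * 2 * 7 * 4096 * 8
    assert o["X1"]["bytes"] == 64 * 2 * 6 * 4096 * 8
    assert o["rotation_keys"]["bytes"] == 2 * 2 * 22 * 22 * 4096 * 8
    assert o["secret_key"]["bytes"] == 2 * 22 * 4096 * 8


@pytest.fixture(scope="module")
def ser_ctx():
    chain = generate_modulus_chain(30, 64, 4)
    ctx = CkksContext(chain, seed=0)
    ctx.keygen(rotation_indices=(1,), relin_powers=(2,))
    return ctx


def test_serialization_roundtrips(tmp_path, ser_ctx):
    ctx, chain = ser_ctx, ser_ctx.chain
    v = np.linspace(-1, 1, 32)
    ct = ctx.encrypt(ctx.encode(v, 4, Fraction(2) ** 30))
    p = str(tmp_path / "ct.bin")
    payload = ser.write_ciphertext(p, ct)
    assert payload == sizeof_ciphertext(4, chain)
    back = ser.read_ciphertext(p, chain)
    assert back.scale == ct.scale and back.tag == ct.tag
    for a, b in zip(ct.polys, back.polys):
        assert np.array_equal(a.residues, b.residues)
    assert np.max(np.abs(np.real(ctx.decrypt_vector(back)) - v)) < 1e-5

    swk = ctx.keys.rot_keys[1]
    sp = str(tmp_path / "swk.bin")
    assert ser.write_switchkey(sp, swk) == sizeof_switchkey(4, chain)
    back_k = ser.read_switchkey(sp, chain)
    for (b1, a1), (b2, a2) in zip(swk.pairs, back_k.pairs):
        assert np.array_equal(b1.residues, b2.residues)
        assert np.array_equal(a1.residues, a2.residues)

    kp = str(tmp_path / "sk.bin")
    assert ser.write_secret_key(kp, ctx.keys.sk) == sizeof_secret_key(chain)
    assert np.array_equal(ser.read_secret_key(kp, chain).residues,
                          ctx.keys.sk.residues)

    cp = str(tmp_path / "chain.json")
    ser.save_chain(cp, chain)
    chain2 = ser.load_chain(cp)
    assert list(chain2.primes) == list(chain.primes)
    # a foreign chain is rejected
    other = generate_modulus_chain(30, 32, 4)
    with pytest.raises(ValueError):
        ser.read_ciphertext(p, other)


def test_cli_plain_and_compare_smoke(tmp_path):
    runner = CliRunner()
    prefix = str(tmp_path / "cohort")
    r = runner.invoke(cli_main, ["simulate", "--out", prefix,
                                 "--n-individuals", "40", "--n-snps", "30",
                                 "--n-causal", "3", "--seed", "1"])
    assert r.exit_code == 0, r.output
    res = str(tmp_path / "plain.tsv")
    r = runner.invoke(cli_main, ["run-plain", "--data", prefix,
                                 "--out", res])
    assert r.exit_code == 0, r.output
    report = str(tmp_path / "rep.json")
    r = runner.invoke(cli_main, ["compare", "--reference", res,
                                 "--pipeline", res, "--out", report])
    assert r.exit_code == 0, r.output
    with open(report) as fh:
        assert json.load(fh)["f1"] == 1.0


def test_cli_cipher_workflow_and_storage(tmp_path):
    runner = CliRunner()
    keys = str(tmp_path / "keys")
    r = runner.invoke(cli_main, ["keygen", "--out", keys, "--n", "128",
                                 "--limbs", "3", "--scale-bits", "35"])
    assert r.exit_code == 0, r.output
    import pandas as pd
    vals = str(tmp_path / "v.tsv")
    v = np.linspace(-1, 1, 16)
    pd.DataFrame({"value": v}).to_csv(vals, sep="\t", index=False)
    ct, ct2, dec = (str(tmp_path / x) for x in ("a.bin", "b.bin", "d.tsv"))
    for args in (["encrypt", "--keys", keys, "--in", vals, "--out", ct],
                 ["eval", "--keys", keys, "--in", ct, "--out", ct2,
                  "--op", "square"],
                 ["decrypt", "--keys", keys, "--in", ct2, "--out", dec,
                  "--count", "16"]):
        r = runner.invoke(cli_main, args)
        assert r.exit_code == 0, r.output
    got = pd.read_csv(dec, sep="\t")["value"].to_numpy()
    assert np.max(np.abs(got - v ** 2)) < 1e-3

    r = runner.invoke(cli_main, ["report-storage", "--profile", "paper"])
    assert r.exit_code == 0, r.output
    assert "0.84 GiB" in r.output and "2.87 GiB" in r.output
    assert "3.65 GiB" in r.output and "8.5 MiB" in r.output
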