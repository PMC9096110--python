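import numpy as np
import pytest
from scipy.special import expit

from ahtpscreen import (FeatureMatrix, FeatureSchema, extract_features,
                        extract_matrix, evaluate_composite,
                        evaluate_composite_on_values, fit_composite,
                        frozen_composites)
from ahtpscreen.composite import (CompositeFeatureSpec, augment_matrix,
                                  augment_schema)
from ahtpscreen.peptide_io import NEGATIVE_LABEL, POSITIVE_LABEL
from ahtpscreen.tables import EISENBERG


def zeros_for(spec):
    return {n: 0.0 for n in spec.coefficients}


def test_frozen_intercepts():
    fr = frozen_composites()
    assert evaluate_composite_on_values(fr["comF"], zeros_for(fr["comF"])) == 0.8634
    assert evaluate_composite_on_values(fr["comF2"], zeros_for(fr["comF2"])) == 0.1786


@pytest.mark.parametrize("name,feature,coef", [
    ("comF2", "Pse_PC13", 2.0823),
    ("comF2", "APAAC1_15", 0.1522),
    ("comF2", "CTDC10", -2.2951),
    ("comF2", "CTDD49", -0.0065),
    ("comF2", "QSO19", 0.2176),
    ("comF", "tscales4", -0.157),
    ("comF", "CTDC19", -0.154),
    ("comF", "hydrophobicity", -0.12),
])
def test_frozen_coefficient_perturbations(name, feature, coef):
    spec = frozen_composites()[name]
    base = zeros_for(spec)
    bumped = dict(base, **{feature: 1.0})
    delta = (evaluate_composite_on_values(spec, bumped)
             - evaluate_composite_on_values(spec, base))
    assert delta == pytest.approx(coef, abs=1e-12)


def test_evaluate_on_feature_vector(ylyelr):
    fv = extract_features(ylyelr)
    spec = frozen_composites()["comF2"]
    manual = spec.intercept + sum(c * fv[n] for n, c in spec.coefficients.items())
    assert evaluate_composite(spec, fv) == pytest.approx(manual)
    # the comF hydrophobicity alias resolves to the Eisenberg residue mean
    comf = frozen_composites()["comF"]
    h_mean = sum(EISENBERG[a] for a in ylyelr.seq) / len(ylyelr)
    manual = comf.intercept + sum(
        c * (h_mean if n == "hydrophobicity" else fv[n])
        for n, c in comf.coefficients.items())
    assert evaluate_composite(comf, fv) == pytest.approx(manual)


def test_evaluate_missing_feature_errors():
    spec = CompositeFeatureSpec("c", 1.0, {"x1": 2.0})
    with pytest.raises(KeyError, match="missing"):
        evaluate_composite_on_values(spec, {})


def test_composite_linearity():
    rng = np.random.default_rng(3)
    spec = CompositeFeatureSpec("c", 0.7, {"a": 1.3, "b": -2.1, "c": 0.4})
    for _ in range(20):
        v = dict(zip("abc", rng.standard_normal(3)))
        w = dict(zip("abc", rng.standard_normal(3)))
        alpha = rng.random()
        mix = {k: alpha * v[k] + (1 - alpha) * w[k] for k in v}
        assert evaluate_composite_on_values(spec, mix) == pytest.approx(
            alpha * evaluate_composite_on_values(spec, v)
            + (1 - alpha) * evaluate_composite_on_values(spec, w), abs=1e-12)


def _logistic_matrix(n, seed, b0=0.5, b1=1.0, b2=-2.0):
    rng = np.random.default_rng(seed)
    x1, x2 = rng.standard_normal(n), rng.standard_normal(n)
    p = expit(b0 + b1 * x1 + b2 * x2)
    y = np.where(rng.random(n) < p, POSITIVE_LABEL, NEGATIVE_LABEL)
    schema = FeatureSchema(blocks=(("sim", ("x1", "x2")),))
    import pandas as pd
    frame = pd.DataFrame({"x1": x1, "x2": x2, "label": y},
                         index=[f"s{i}" for i in range(n)])
    return FeatureMatrix(schema=schema, frame=frame)


def test_fit_recovers_generating_coefficients():
    m = _logistic_matrix(5000, seed=42)
    fit = fit_composite(m, ["x1", "x2"], name="sim", seed=0)
    assert fit.converged
    assert fit.spec.intercept == pytest.approx(0.5, abs=0.15)
    assert fit.spec.coefficients["x1"] == pytest.approx(1.0, abs=0.15)
    assert fit.spec.coefficients["x2"] == pytest.approx(-2.0, abs=0.15)


def test_fit_deterministic():
    m = _logistic_matrix(500, seed=1)
    f1 = fit_composite(m, ["x1", "x2"], name="sim", seed=5)
    f2 = fit_composite(m, ["x1", "x2"], name="sim", seed=5)
    assert f1.spec == f2.spec


def test_fit_sign_pattern_recovery_over_seeds():
    hits = 0
    for seed in range(10):
        m = _logistic_matrix(2000, seed=seed)
        fit = fit_composite(m, ["x1", "x2"], name="sim", seed=0)
        if fit.spec.coefficients["x1"] > 0 > fit.spec.coefficients["x2"]:
            hits += 1
    assert hits >= 10 * 0.95


def test_fit_flags_separable_data():
    import pandas as pd
    n = 60
    x = np.r_[np.linspace(-2, -0.5, n // 2), np.linspace(0.5, 2, n // 2)]
    y = np.r_[[NEGATIVE_LABEL] * (n // 2), [POSITIVE_LABEL] * (n // 2)]
    schema = FeatureSchema(blocks=(("sim", ("x1",)),))
    m = FeatureMatrix(schema=schema, frame=pd.DataFrame(
        {"x1": x, "label": y}, index=[f"s{i}" for i in range(n)]))
    with pytest.warns(UserWarning, match="diverging|converge"):
        fit = fit_composite(m, ["x1"], name="sep", regularization=0, seed=0)
    assert fit.separable_warning or not fit.converged


def test_fit_single_class_errors():
    m = _logistic_matrix(100, seed=0)
    m.frame["label"] = POSITIVE_LABEL
    with pytest.raises(ValueError, match="both classes"):
        fit_composite(m, ["x1", "x2"], name="bad")


def test_augment_schema_and_matrix(small_dataset):
    m = extract_matrix(small_dataset)
    specs = list(frozen_composites().values())
    schema2 = augment_schema(m.schema, specs)
    assert schema2.dimension == 433
    assert augment_schema(m.schema, []).dimension == 431
    m2 = augment_matrix(m, specs)
    assert m2.schema.dimension == 433
    # the appended column equals evaluate_composite on each base vector
    for pid in m.frame.index[:3]:
        row = m.frame.loc[pid]
        fv_vals = {n: row[n] for n in m.schema.names}
        fv_vals["hydrophobicity"] = sum(
            EISENBERG[a] * row[f"AAC{i + 1}"]
            for i, a in enumerate(sorted(EISENBERG)))
        expected = evaluate_composite_on_values(specs[1], fv_vals)
        assert m2.frame.at[pid, "comF2"] == pytest.approx(expected)
    with pytest.raises(ValueError, match="collision"):
        augment_matrix(m2, specs)
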