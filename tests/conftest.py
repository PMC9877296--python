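import numpy as np
import pytest

from mirdisnet import ClassifierConfig, ExpressionDataset, GroupTable

# Worked-example association rows (disease -> listed members, one pair per row
# when written to disk).  The Embryonal row lists hsa-mir-29c twice on purpose.
EXAMPLE_ASSOCIATIONS = [
    ("Alopecia", "hsa-mir-106b"),
    ("Alopecia", "hsa-mir-125b-1"),
    ("Alopecia", "hsa-mir-125b-2"),
    ("Alopecia", "hsa-mir-221"),
    ("Alopecia", "hsa-mir-410"),
    ("Alopecia", "hsa-mir-203"),
    ("Alopecia", "hsa-mir-575"),
    ("Alopecia", "hsa-mir-602"),
    ("Alopecia", "hsa-mir-106a"),
    ("Alopecia", "hsa-mir-125b"),
    ("Acute Brucellosis", "hsa-mir-126"),
    ("Acute Brucellosis", "hsa-mir-4753"),
    ("Cataract", "hsa-mir-184"),
    ("Cataract", "hsa-mir-125b"),
    ("Cataract", "hsa-mir-589"),
    ("Cataract", "hsa-mir-326"),
    ("Cataract", "hsa-mir-675"),
    ("Cataract", "hsa-mir-34a"),
    ("Cataract", "hsa-mir-15a"),
    ("Carcinoma, Embryonal", "hsa-mir-372"),
    ("Carcinoma, Embryonal", "hsa-mir-373"),
    ("Carcinoma, Embryonal", "hsa-mir-29c"),
    ("Carcinoma, Embryonal", "hsa-mir-19"),
    ("Carcinoma, Embryonal", "hsa-mir-29c"),
    ("Carcinoma, Embryonal", "hsa-mir-134"),
    ("Carcinoma, Embryonal", "hsa-mir-140"),
    ("Carcinoma, Embryonal", "hsa-mir-302b"),
    ("Carcinoma, Embryonal", "hsa-mir-27"),
    ("Carcinoma, Embryonal", "hsa-mir-34a"),
    ("Carcinoma, Embryonal", "hsa-mir-601"),
    ("Pancreatic Diseases", "hsa-let-7b"),
    ("Pancreatic Diseases", "hsa-mir-495"),
]

# Worked-example scoring output: eight (disease, mean accuracy) pairs whose
# printed dense ranks are (1,1,1,1,2,2,2,3).
EXAMPLE_SCORES = [
    ("Graft-versus-host disease", 0.9636),
    ("Human immunodeficiency virus infection", 0.9636),
    ("Hypertrophy", 0.9636),
    ("Kaposi sarcoma", 0.9636),
    ("Bladder carcinoma", 0.9454),
    ("Acute promyelocytic leukemia", 0.9454),
    ("Ischemia-reperfusion injury", 0.9454),
    ("Oral squamous cell carcinoma", 0.9272),
]


def build_ds(values, labels, features=None, samples=None) -> ExpressionDataset:
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return ExpressionDataset(
        sample_ids=samples or [f"s{i}" for i in range(n)],
        feature_ids=features or [f"mir-{j:03d}" for j in range(m)],
        values=values,
        labels=np.asarray(labels, dtype=object),
    )


@pytest.fixture
def make_ds():
    return build_ds


@pytest.fixture
def example_groups() -> GroupTable:
    groups: dict[str, set[str]] = {}
    for disease, mirna in EXAMPLE_ASSOCIATIONS:
        groups.setdefault(disease, set()).add(mirna)
    return GroupTable(groups={k: frozenset(v) for k, v in groups.items()})


@pytest.fixture
def example_associations_file(tmp_path):
    path = tmp_path / "associations.tsv"
    path.write_text(
        "".join(f"{d}\t{m}\n" for d, m in EXAMPLE_ASSOCIATIONS), encoding="utf-8"
    )
    return path


@pytest.fixture
def fast_cfg() -> ClassifierConfig:
    """Small forest: statistical behaviour is the same, tests stay fast."""
    return ClassifierConfig(trees=10)


@pytest.fixture
def separable_ds(make_ds) -> ExpressionDataset:
    """One feature at 10 for every pos sample and 0 for every neg sample."""
    rng = np.random.default_rng(7)
    n = 20
    values = np.column_stack(
        [
            np.where(np.arange(n) < 10, 10.0, 0.0),
            rng.normal(5.0, 1.0, n) ** 2,
        ]
    )
    return make_ds(values, ["pos"] * 10 + ["neg"] * 10)
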