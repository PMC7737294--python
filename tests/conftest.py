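import pandas as pd
import pytest

from fusioncurate import CohortRecipe, generate_cohort, run_from_directory
from fusioncurate.io_standardization import STANDARD_COLUMNS, ExpressionMatrix

_DEFAULTS = {
    "Sample": "S1",
    "Gene2A": None,
    "Gene2B": None,
    "LeftBreakpoint": "1:1000",
    "RightBreakpoint": "2:2000",
    "LeftStrand": "+",
    "RightStrand": "+",
    "Fusion_Type": "in-frame",
    "Caller": "STARFUSION",
    "JunctionReadCount": 10,
    "SpanningFragCount": 15,
    "Confidence": None,
    "annots": "",
}


def make_calls(rows):
    """Build a standardized call table from partial row dicts."""
    full = []
    for row in rows:
        rec = dict(_DEFAULTS)
        rec.update(row)
        rec.setdefault("FusionName", f"{rec.get('Gene1A', 'A')}--{rec.get('Gene1B', 'B')}")
        rec.setdefault("Gene1A", rec["FusionName"].split("--")[0])
        rec.setdefault("Gene1B", rec["FusionName"].split("--")[1])
        full.append(rec)
    df = pd.DataFrame(full, columns=STANDARD_COLUMNS)
    df["JunctionReadCount"] = df["JunctionReadCount"].astype("int64")
    df["SpanningFragCount"] = df["SpanningFragCount"].astype("int64")
    return df


def make_expression(gene_values, samples=("S1",)):
    """ExpressionMatrix with the same value for a gene across samples,
    or per-sample dicts."""
    rows = {}
    for gene, value in gene_values.items():
        if isinstance(value, dict):
            rows[gene] = {s: value.get(s, float("nan")) for s in samples}
        else:
            rows[gene] = {s: value for s in samples}
    df = pd.DataFrame(rows).T
    df.columns = list(samples)
    df.index.name = "GeneSymbol"
    return ExpressionMatrix(values=df)


@pytest.fixture
def calls_factory():
    return make_calls


@pytest.fixture
def expression_factory():
    return make_expression


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory):
    """Default synthetic cohort (10 groups x 10 samples) plus its manifest."""
    out = tmp_path_factory.mktemp("cohort")
    manifest = generate_cohort(CohortRecipe(seed=7), out)
    return out, manifest


@pytest.fixture(scope="session")
def default_result(default_cohort):
    out, _ = default_cohort
    return run_from_directory(out)
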