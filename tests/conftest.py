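import pytest

from pmcindex import builtin_schema, builtin_score_table, evaluate_all


@pytest.fixture(scope="session")
def schema():
    return builtin_schema()


@pytest.fixture(scope="session")
def table(schema):
    return builtin_score_table(schema)


@pytest.fixture(scope="session")
def results(table):
    return evaluate_all(table)


@pytest.fixture(scope="session")
def by_policy(results):
    return {r.policy: r for r in results}
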