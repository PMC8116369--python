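import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy import stats

from promisgh.grm import category_probabilities, load_default_parameters
from promisgh.instrument import ResponseRecord, load_default_instrument

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def spec():
    return load_default_instrument()


@pytest.fixture(scope="session")
def params():
    return load_default_parameters()


@pytest.fixture(scope="session")
def gph_items(spec, params):
    return [params[i] for i in spec.subscale_items("GPH")]


@pytest.fixture(scope="session")
def gmh_items(spec, params):
    return [params[i] for i in spec.subscale_items("GMH")]


def dense_eap(responses, items, lo=-8.0, hi=8.0, n=10001):
    """Independent EAP oracle: trapezoid integration on a dense grid."""
    nodes = np.linspace(lo, hi, n)
    post = stats.norm.pdf(nodes)
    for resp, item in zip(responses, items):
        if resp is None:
            continue
        post = post * category_probabilities(item, nodes)[:, resp - 1]
    mean = np.trapezoid(nodes * post, nodes) / np.trapezoid(post, nodes)
    var = np.trapezoid((nodes - mean) ** 2 * post, nodes) / np.trapezoid(post, nodes)
    return float(mean), float(np.sqrt(var))


def make_record(rid="R1", age=30, gender="female", responses=None, **demo):
    return ResponseRecord(
        respondent_id=rid,
        age=age,
        gender=gender,
        education=demo.get("education", "middle"),
        region=demo.get("region", "west"),
        ethnicity=demo.get("ethnicity", "native"),
        raw_responses=responses or {},
    )
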