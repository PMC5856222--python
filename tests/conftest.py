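import datetime
from decimal import Decimal

import pytest
from hypothesis import HealthCheck, settings

from quitcost import CostedRecord, ServiceRecord

settings.register_profile(
    "ci", derandomize=True,
    # the record factories are stateless, so sharing them across generated
    # inputs is safe
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def make_record():
    """Factory for valid post-exclusion-style records with overridable fields."""

    def _make(**overrides) -> ServiceRecord:
        base = dict(
            client_id="C000001",
            quit_date=datetime.date(2015, 6, 1),
            pregnant=False,
            treatments=frozenset({"NRT"}),
            pathway="other",
            doses_dispensed=6,
            contact_minutes=90.0,
            quit_12wk=1,
            age_years=40,
            gender="female",
            ftnd=5,
            imd_raw=4,
            region="Sandwell",
        )
        base.update(overrides)
        return ServiceRecord(**base)

    return _make


@pytest.fixture
def make_costed(make_record):
    """Factory for costed records with an exact chosen total cost and quit
    status, for ratio/bootstrap tests where penny-exact group sums matter."""

    def _make(total_cost, quit: int, **overrides) -> CostedRecord:
        rec = make_record(doses_dispensed=0, quit_12wk=quit, **overrides)
        total = Decimal(str(total_cost)).quantize(Decimal("0.01"))
        return CostedRecord(record=rec, medication_cost=Decimal("0.00"),
                            adviser_cost=total, total_cost=total,
                            doses_costed=0)

    return _make
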