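import pytest
from hypothesis import HealthCheck, settings

from paleotherm import OccurrenceRecord, ThermalRange

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def make_record():
    """Factory for valid occurrence records with overridable fields."""

    counter = {"n": 0}

    def _make(
        t_min=18.0,
        t_max=21.0,
        stage="Pragian",
        paleolat=22.0,
        taxon="Favosites_sp",
        depth_class="shallow",
        collection=None,
        **kwargs,
    ):
        counter["n"] += 1
        return OccurrenceRecord(
            record_id=f"r{counter['n']:05d}",
            collection_id=collection or f"c{counter['n'] % 7}",
            taxon_name=taxon,
            stage=stage,
            paleolat=paleolat,
            thermal=ThermalRange(t_min=t_min, t_max=t_max),
            depth_class=depth_class,
            **kwargs,
        )

    return _make


@pytest.fixture
def occ_csv(tmp_path):
    """Write a flat occurrence CSV from a list of row dicts; returns path."""
    import pandas as pd

    def _write(rows, name="occ.csv", **to_csv_kwargs):
        path = tmp_path / name
        pd.DataFrame(rows).to_csv(path, index=False, **to_csv_kwargs)
        return path

    return _write
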