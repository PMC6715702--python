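import numpy as np
import pytest

from morphnet.cohort import CohortTable, ScanRecord
from morphnet.network import CorrelationNetwork

#: raw measurements for a well-formed scan; chosen so every registered
#: parameter is present and all denominators are positive
BASE_MEASUREMENTS = {
    "brain_length": 80.0,
    "brain_width": 55.0,
    "cerebellar_compression_index": 0.35,
    "cerebellar_compression_length": 10.5,
    "cerebellar_diameter": 40.0,
    "cerebellar_volume": 10000.0,
    "corpus_callosum_angle": 25.0,
    "corpus_callosum_thickness": 3.0,
    "cranial_length": 100.0,
    "interthalamic_adhesion_height": 6.0,
    "obex_position": 3.5,
    "sulcus_depth": 5.0,
    "total_brain_volume": 100000.0,
    "ventricular_volume": 5000.0,
    "head_angle": 35.0,
    "ventricle_height": 0.0,
    "muzzle_length": 50.0,
}


def make_scan(scan_id="s1", **overrides):
    measurements = dict(BASE_MEASUREMENTS)
    measurements.update(overrides.pop("measurements", {}))
    defaults = dict(
        scan_id=scan_id,
        patient_id=f"p_{scan_id}",
        measurements=measurements,
        body_weight=20.0,
        age=5.0,
        sex="female",
        neutered=False,
        breed="Labrador Retriever",
        breed_group="Gundog",
        diagnostic_class="normal",
        purebred=True,
        clade="Retriever",
    )
    defaults.update(overrides)
    return ScanRecord(**defaults)


def make_cohort(n=5, jitter_seed=0, **common):
    """Cohort of n scans with slightly jittered measurements."""
    rng = np.random.default_rng(jitter_seed)
    records = []
    for i in range(n):
        noise = {
            k: v * (1 + 0.05 * rng.standard_normal())
            for k, v in BASE_MEASUREMENTS.items()
            if k not in ("ventricle_height",)
        }
        noise["ventricle_height"] = float(rng.choice([0.0, 2.0, 7.0]))
        records.append(
            make_scan(scan_id=f"s{i + 1:03d}", measurements=noise, **common)
        )
    return CohortTable(records=records)


def net_from_edges(edges, excluded=(), threshold=0.0):
    nodes = sorted({x for a, b, _ in edges for x in (a, b)})
    return CorrelationNetwork(
        nodes=nodes,
        edges=list(edges),
        threshold=threshold,
        excluded_nodes=list(excluded),
    )


def clique_edges(names, weight=1.0):
    return [
        (a, b, weight) for i, a in enumerate(names) for b in names[i + 1:]
    ]


@pytest.fixture
def small_cohort():
    return make_cohort(n=8)
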