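import numpy as np
import pandas as pd
import pytest

from rrhosig.dataset import FO, PO, ExpressionDataset
from rrhosig.ranking import RankedList
from rrhosig.simulate import SimulationConfig, generate_study


def make_dataset(values, genes=None, classes=None, survival=None, platform_id="T"):
    """Small hand-built dataset; rows indexed g0..gN unless genes given."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    probes = [f"g{i}" for i in range(n_probes)] if genes is None else list(genes)
    samples = [f"s{i}" for i in range(n_samples)]
    if classes is None:
        half = n_samples // 2
        classes = [FO] * half + [PO] * (n_samples - half)
    surv = None
    if survival is not None:
        surv = pd.DataFrame(survival, index=samples, columns=["time", "event"])
    return ExpressionDataset(
        values=pd.DataFrame(values, index=probes, columns=samples),
        probe_to_gene=pd.Series(probes, index=probes),
        sample_classes=pd.Series(classes, index=samples),
        survival=surv,
        platform_id=platform_id,
    )


def ranked_from_genes(genes, scores=None, dataset_id="L"):
    if scores is None:
        scores = np.arange(len(genes), 0, -1, dtype=float)
    return RankedList(genes=list(genes), scores=np.asarray(scores, float),
                      dataset_id=dataset_id)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_platforms=3,
        genes_per_platform=600,
        shared_gene_fraction=0.7,
        n_signature_genes=40,
        effect_size=2.0,
        n_fo=10,
        n_po=10,
        n_contaminated_fo=2,
        contamination_boost=8.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)
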