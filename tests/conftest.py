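import numpy as np
import pandas as pd
import pytest

from crossmodulon import compendium as comp
from crossmodulon.synth import (
    SynthConfig,
    generate_ground_truth,
    generate_matched_compendia,
)


@pytest.fixture(scope="session")
def small_config():
    # compact study: 400 genes, 30 conditions x 2 replicates, 5 ti / 4 pi
    # modules, one lumped pair
    return SynthConfig(
        n_genes=400,
        n_conditions=30,
        k_t=5,
        k_p=4,
        n_lumped=1,
        module_frac_min=0.03,
        module_frac_max=0.05,
    )


@pytest.fixture(scope="session")
def small_gt(small_config):
    return generate_ground_truth(seed=7, config=small_config)


@pytest.fixture(scope="session")
def small_sim(small_gt):
    return generate_matched_compendia(small_gt)


@pytest.fixture(scope="session")
def small_compendia(small_sim):
    """Compiled transcriptome + proteome matrices from the small study."""
    Xt = comp.center_to_reference(small_sim.transcriptome, small_sim.metadata)
    Xp, meta_p, report = comp.compile_compendium(
        small_sim.proteome_abundance, small_sim.metadata
    )
    return Xt, Xp, meta_p, report


@pytest.fixture()
def toy_metadata():
    def make(n_conditions, replicates=2, reference="c0", batch_of=None):
        rows = []
        for c in range(n_conditions):
            for r in range(replicates):
                cid = f"c{c}"
                rows.append(
                    {
                        "sample_id": f"c{c}_r{r + 1}",
                        "condition_id": cid,
                        "replicate": r + 1,
                        "batch": batch_of(cid) if batch_of else "b0",
                        "is_reference": cid == reference,
                    }
                )
        return pd.DataFrame(rows)

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
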