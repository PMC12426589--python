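import numpy as np
import pandas as pd
import pytest

from bruvkit import design, ingest, synthetic
from bruvkit.pipeline import synthetic_lw_registry, synthetic_traits

STRATUM_OF = {1: "Reefs", 2: "Reefs", 3: "Sediments", 4: "Sediments"}


@pytest.fixture(scope="session")
def seascape():
    return synthetic.generate_seascape(7, (0., 0., 8000., 8000.), 100.0)


@pytest.fixture(scope="session")
def frame(seascape):
    return design.frame_from_rasters(seascape.habitat, seascape.bathymetry,
                                     STRATUM_OF)


@pytest.fixture(scope="session")
def plan(frame):
    return design.grts_sample(frame, {"Reefs": 60, "Sediments": 30},
                              min_dist=200.0, depth_range=(0., 40.),
                              seed=7)


@pytest.fixture(scope="session")
def species_pool():
    return synthetic.default_species_pool(12, seed=3)


@pytest.fixture(scope="session")
def survey(plan, seascape, species_pool):
    """One simulated survey reused across test modules."""
    deployments = synthetic.build_deployment_table(plan, seascape, seed=7)
    annotations, truth = synthetic.simulate_annotations(
        deployments, species_pool, n_frames=40, seed=7)
    maxn, maxn_times = ingest.compute_maxn(annotations,
                                           deployments["deployment_id"])
    return {
        "deployments": deployments,
        "annotations": annotations,
        "truth": truth,
        "maxn": maxn,
        "maxn_times": maxn_times,
        "traits": synthetic_traits(species_pool),
        "registry": synthetic_lw_registry(species_pool),
    }


def random_annotations(rng, n_dep=5, n_taxa=8, n_frames=50, p=0.1):
    """Random sparse frame-level annotation table for oracle checks."""
    rows = []
    for d in range(n_dep):
        for t in range(n_taxa):
            for f in range(n_frames):
                if rng.random() < p:
                    rows.append((f"d{d}", float(f * 60), f"taxon_{t}",
                                 int(rng.integers(1, 6)), np.nan, 0))
    return pd.DataFrame(rows, columns=["deployment_id", "time_s", "taxon",
                                       "count", "length_mm", "measurable"])


def brute_force_maxn(annotations):
    """Independent nested-loop MaxN oracle."""
    out = {}
    for (dep, taxon), grp in annotations.groupby(["deployment_id", "taxon"]):
        best = 0
        for t in sorted(grp["time_s"].unique()):
            total = int(grp.loc[grp["time_s"] == t, "count"].sum())
            if total > best:
                best = total
        out[(dep, taxon)] = best
    return out
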