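import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "atlas",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("atlas")


@pytest.fixture(scope="session")
def study_sim():
    """The study-scale simulated atlas (74 loci, 17 chr10 clusters)."""
    from serpin_atlas import synthetic_atlas as sa

    return sa.simulate_atlas(sa.study_scale_config(1))


@pytest.fixture(scope="session")
def study_atlas(study_sim):
    """Full pipeline result on the study-scale simulation."""
    from serpin_atlas.pipeline import build_atlas

    return build_atlas(
        study_sim.genome, study_sim.genes, study_sim.seeds, study_sim.seed_p1_offsets
    )


def small_config(seed=7):
    """A 5-locus, 2-chromosome configuration for fast unit tests."""
    from serpin_atlas.synthetic_atlas import AtlasSimConfig, DecoyPlan, LocusPlan

    features = [
        LocusPlan(name="S1c1", chromosome="chrA", strand="+", gap_before=5_000,
                  rcl_seed_id="rcl_R", rcl_mismatches=0, cluster_id="a1"),
        LocusPlan(name="S2c1", chromosome="chrA", strand="-", gap_before=20_000,
                  rcl_seed_id="rcl_S", rcl_mismatches=2, cluster_id="a1",
                  architecture="two_exon", intron_length=800),
        DecoyPlan(name="d1", chromosome="chrA", gap_before=60_000),
        LocusPlan(name="S3c1", chromosome="chrA", strand="-", gap_before=60_000,
                  rcl_seed_id="rcl_Vdual", rcl_mismatches=1, cluster_id=None),
        LocusPlan(name="S4c2", chromosome="chrB", strand="+", gap_before=8_000,
                  rcl_seed_id="rcl_K", rcl_mismatches=3, cluster_id=None,
                  architecture="two_exon", intron_length=600),
        DecoyPlan(name="d2", chromosome="chrB", gap_before=4_000),
        LocusPlan(name="S5c2", chromosome="chrB", strand="-", gap_before=150_000,
                  rcl_seed_id="rcl_N", rcl_mismatches=0, cluster_id=None),
    ]
    return AtlasSimConfig(
        chromosomes={"chrA": 0, "chrB": 0}, features=features, seed=seed, margin=2_000
    )


@pytest.fixture(scope="module")
def small_sim():
    from serpin_atlas.synthetic_atlas import simulate_atlas

    return simulate_atlas(small_config())
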