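import pytest

from beelecty.synth import SyntheticConfig, generate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced synthetic bundle shared by module tests (150 species)."""
    cfg = SyntheticConfig(
        n_species=150,
        n_bee_genera=25,
        n_plant_families=15,
        records_mean=40.0,
        occ_mean=30.0,
        seed=42,
    )
    return generate_bundle(cfg)


@pytest.fixture(scope="session")
def small_feature_table(small_bundle):
    from beelecty.features import build_feature_table
    from beelecty.filtering import (
        dedupe_occurrences,
        filter_visitation,
        remove_geographic_outliers,
    )

    b = small_bundle
    vis, _ = filter_visitation(
        b.visitation,
        us_species=b.us_species,
        cleptoparasites=b.cleptoparasites,
        nonnatives=b.nonnatives,
        labeled_species={l.bee_species for l in b.labels},
    )
    occ, _ = dedupe_occurrences(b.occurrences)
    occ, _ = remove_geographic_outliers(occ)
    table, _ = build_feature_table(
        vis, occ, b.labels, b.bee_tree, b.plant_tree, seed=42
    )
    return table
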