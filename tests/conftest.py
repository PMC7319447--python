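import pytest

from mirnet.annotation_io import MatureMiRNA, PrecursorLocus, extract_seed
from mirnet.synthetic_fixtures import FixtureSpec, write_fixture_files


def make_mature(name: str, sequence: str, species: str = "syn") -> MatureMiRNA:
    return MatureMiRNA(name, species, sequence, extract_seed(sequence))


def make_locus(lid, chrom, start, end, strand="+", mature_ids=()):
    return PrecursorLocus(lid, chrom, start, end, strand, list(mature_ids))


@pytest.fixture
def seed_families():
    """3 matures sharing seed AGCACC, 2 sharing CCCGGG, 1 singleton."""
    return [
        make_mature("syn-miR-1a-5p", "UAGCACCAUCUGAAAUCGGUUA"),
        make_mature("syn-miR-1b-5p", "CAGCACCGGGUAAAGUCGGUUA"),
        make_mature("syn-miR-1c-5p", "GAGCACCUUUCCCAAAGGGUUA"),
        make_mature("syn-miR-2a-3p", "ACCCGGGAUCUGAAAUCGGUUA"),
        make_mature("syn-miR-2b-3p", "UCCCGGGUUCUGAAAUCGGUUA"),
        make_mature("syn-miR-3-5p", "AGGGUUUAUCUGAAAUCGGUUA"),
    ]


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A small generated dataset written to disk once per session."""
    spec = FixtureSpec(
        rng_seed=11,
        family_sizes=(4, 3, 2),
        n_singletons=6,
        n_genomic_clusters=3,
        planted_groups=((("family", 0), 0.95),),
        background_hit_probability=0.1,
    )
    out = tmp_path_factory.mktemp("fixture")
    paths = write_fixture_files(spec, out)
    return spec, paths
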