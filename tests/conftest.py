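import importlib.resources as ir
import io
import warnings

import pytest
from hypothesis import HealthCheck, settings

from mitocomp import codon_usage as cu
from mitocomp import gene_order as go
from mitocomp import model
from mitocomp import synthetic as syn

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

DATA = ir.files("mitocomp") / "data"


def data_text(name: str) -> str:
    return (DATA / name).read_text(encoding="utf-8")


@pytest.fixture(scope="session")
def table2():
    """The published G. albolineatus annotation table, parsed leniently."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", model.AnnotationWarning)
        return model.parse_feature_table(
            io.StringIO(data_text("grapsus_albolineatus_annotation.tsv")))


@pytest.fixture(scope="session")
def table3_rows():
    """Published multi-taxon composition table as a list of dicts."""
    lines = data_text("brachyura_composition.tsv").strip().splitlines()
    hdr = lines[0].split("\t")
    return [dict(zip(hdr, ln.split("\t"))) for ln in lines[1:]]


@pytest.fixture(scope="session")
def table4_usage():
    """Published codon counts with RSCU computed by this package."""
    usage = cu.read_codon_counts(
        io.StringIO(data_text("grapsus_albolineatus_codons.tsv")))
    return cu.rscu(usage)


@pytest.fixture(scope="session")
def table4_printed():
    """Codon -> printed RSCU value from the published table."""
    lines = data_text("grapsus_albolineatus_codons.tsv").strip().splitlines()
    out = {}
    for ln in lines[1:]:
        codon, _count, rscu_s = ln.split("\t")
        out[codon] = float(rscu_s)
    return out


@pytest.fixture(scope="session")
def fixture_orders():
    return go.read_orders(io.StringIO(data_text("gene_orders.txt")))


@pytest.fixture(scope="session")
def albolineatus_order(fixture_orders):
    return next(o for o in fixture_orders if o.taxon == "G_albolineatus")


@pytest.fixture(scope="session")
def default_genome():
    """One seeded synthetic genome at the default study conditions."""
    return syn.generate_genome(syn.GenomeSpec(seed=11))
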