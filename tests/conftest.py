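import hypothesis
import numpy as np
import pandas as pd
import pytest

from perconet import OtuTable

hypothesis.settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("default")


@pytest.fixture
def toy_table() -> OtuTable:
    """3 OTUs x 4 samples with one singleton and one rare OTU."""
    counts = pd.DataFrame(
        {
            "s1": [5, 1, 0, 2],
            "s2": [3, 0, 0, 4],
            "s3": [0, 0, 1, 6],
            "s4": [7, 0, 0, 8],
        },
        index=["otuA", "otuB", "otuC", "otuD"],
    )
    taxonomy = pd.Series(
        {
            "otuA": "Bacteria;Firmicutes;Clostridia;Clostridiales;Ruminococcaceae;Ruminiclostridium",
            "otuB": "Archaea;Thermoplasmatota;Thermoplasmata;Methanomassiliicoccales;Methanomassiliicoccaceae;Methanomassiliicoccus",
            "otuC": "Bacteria;Unclassified;Unclassified;Unclassified;Unclassified;Unclassified",
            "otuD": "Bacteria;Bacteroidota;Bacteroidia;Bacteroidales;Dysgonomonadaceae;Dysgonomonas",
        }
    )
    samples = pd.DataFrame(
        {"group": ["PENF", "PENF", "DOUR", "DOUR"], "timepoint": [0, 1, 0, 1]},
        index=["s1", "s2", "s3", "s4"],
    )
    return OtuTable(counts=counts, taxonomy=taxonomy, samples=samples)


@pytest.fixture
def write_table_files(tmp_path):
    """Write an OtuTable to counts/taxonomy/metadata TSVs; returns the paths."""

    def _write(table: OtuTable):
        counts_path = tmp_path / "counts.tsv"
        tax_path = tmp_path / "taxonomy.tsv"
        meta_path = tmp_path / "metadata.tsv"
        table.counts.rename_axis("otu_id").to_csv(counts_path, sep="\t")
        table.taxonomy.rename("lineage").rename_axis("otu_id").to_csv(
            tax_path, sep="\t"
        )
        table.samples.rename_axis("sample_id").to_csv(meta_path, sep="\t")
        return counts_path, tax_path, meta_path

    return _write


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231201)
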