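import pandas as pd
import pytest

from clonetrack.data_model import REPLICATE_ID
from clonetrack.synthetic_fixtures import ScenarioConfig, generate_scenario


def make_long(rows, kind="seqCount"):
    """Long IS matrix from (chr, locus, strand, replicate, value[, gene]) tuples."""
    recs = []
    for r in rows:
        chrom, locus, strand, rid, value = r[:5]
        gene = r[5] if len(r) > 5 else None
        recs.append(
            {
                "chr": str(chrom),
                "integration_locus": int(locus),
                "strand": strand,
                "GeneName": gene,
                "GeneStrand": "+" if gene else None,
                REPLICATE_ID: rid,
                "kind": kind,
                "value": float(value),
            }
        )
    return pd.DataFrame(recs)


def make_meta(rows, **common):
    """Metadata from dicts (must carry the replicate id key) plus shared fields."""
    out = pd.DataFrame([{**common, **r} for r in rows])
    return out


@pytest.fixture(scope="session")
def scenario(tmp_path_factory):
    """Default synthetic scenario with files on disk (shared across tests)."""
    out = tmp_path_factory.mktemp("scenario")
    return generate_scenario(ScenarioConfig(seed=1), out)
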