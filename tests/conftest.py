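import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mirmut.reference_io import MirnaGeneAnnotation

settings.register_profile("default", derandomize=True)
settings.load_profile("default")


@pytest.fixture
def toy_annotation() -> MirnaGeneAnnotation:
    """Deterministic 60-nt precursor with arms at 6-27 (5p) and 34-55 (3p)."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    return MirnaGeneAnnotation(
        gene_id="MIRTOY",
        precursor_id="MIRTOY-pre",
        precursor_seq="".join(rng.choice(bases, size=60)),
        flank5_seq="".join(rng.choice(bases, size=25)),
        flank3_seq="".join(rng.choice(bases, size=25)),
        mature5p_span=(6, 27),
        mature3p_span=(34, 55),
    )


def make_records(rows, sample_id="S1", gene_id="MIRTOY", arm="5p", allele="WT",
                 source="exclusive"):
    """Isomir record frame from (shift5, shift3, nontemplate, count) tuples."""
    return pd.DataFrame(
        [
            {
                "sample_id": sample_id, "gene_id": gene_id, "arm": arm,
                "shift5": s5, "shift3": s3, "nontemplate": nt,
                "allele": allele, "source": source, "count": n, "rpm": float(n),
            }
            for s5, s3, nt, n in rows
        ]
    )


@pytest.fixture
def record_factory():
    return make_records
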