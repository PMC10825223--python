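import numpy as np
import pandas as pd
import pytest

from rbekit.simdata import (
    EnzymeModel,
    TranscriptomeSpec,
    build_reporter,
    simulate_reads,
    simulate_transcriptome,
)


@pytest.fixture(scope="session")
def small_transcriptome():
    spec = TranscriptomeSpec(
        n_genes=12,
        length_model={"cds_mean": 300, "cds_sd": 30, "utr3_mean": 300, "utr3_sd": 30},
        seed=7,
    )
    return simulate_transcriptome(spec)


@pytest.fixture(scope="session")
def reporter_spec():
    return build_reporter("MS2x12", seed=1)


@pytest.fixture(scope="session")
def basic_enzyme():
    return EnzymeModel(
        name="c2u",
        edit_type="C2U",
        peak_rate=0.3,
        kernel_halfwidth=15.0,
        background_rate=1e-3,
    )


@pytest.fixture(scope="session")
def reporter_reads(reporter_spec, basic_enzyme):
    reads, truth = simulate_reads(
        {reporter_spec.name: reporter_spec.full_seq},
        {basic_enzyme.name: {reporter_spec.name: reporter_spec.loop_sites("MS2")}},
        [basic_enzyme],
        n_reads=3000,
        seed=5,
        error_rate=0.0,
    )
    return reads, truth


def toy_genes(rows):
    """Gene-model frame from (chrom, start, end, gene_id[, cds_end]) tuples."""
    out = []
    for row in rows:
        chrom, start, end, gid = row[:4]
        cds_end = row[4] if len(row) > 4 else (start + end) // 2
        out.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": "+",
                "gene_id": gid,
                "cds_start": start,
                "cds_end": cds_end,
                "utr3_start": cds_end,
                "utr3_end": end,
                "top": False,
            }
        )
    return pd.DataFrame(out)
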