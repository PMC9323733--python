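import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def make_scan():
    """Factory for hand-built scan tables (one row per spot)."""

    def _make(spots):
        # spots: iterable of (probe_id, gene_id, replicate_index, probe_class,
        #                     intensity_sample, intensity_reference)
        df = pd.DataFrame(spots, columns=[
            "probe_id", "gene_id", "replicate_index", "probe_class",
            "intensity_sample", "intensity_reference"])
        df.insert(0, "condition", "test")
        df.insert(0, "array_id", "array_1")
        return df

    return _make


@pytest.fixture
def make_ratio_table():
    """Factory for probe log-ratio tables as eliminate/summarize expect."""

    def _make(rows):
        # rows: (gene_id, replicate_index, log2_ratio, mean_log2_intensity)
        df = pd.DataFrame(rows, columns=[
            "gene_id", "replicate_index", "log2_ratio", "mean_log2_intensity"])
        df["probe_id"] = df["gene_id"] + "_r" + df["replicate_index"].astype(str)
        df["probe_class"] = "experimental"
        df["floored"] = False
        df["outlier_flag"] = False
        return df

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
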