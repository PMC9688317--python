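import numpy as np
import pandas as pd
import pytest

import synscreen as ss


@pytest.fixture(scope="session")
def small_library() -> ss.BarcodeLibrary:
    """10 genes x 5 shRNAs, barcode length 18, Hamming distance >= 3."""
    return ss.make_library(10, 5, barcode_length=18, seed=42)


@pytest.fixture(scope="session")
def screen_tables(small_library):
    """Simulated control/treated counts with two planted sensitizer genes."""
    params = ss.ScreenSimParams(
        n_genes=10,
        nb_mean=500,
        nb_dispersion=50,
        sensitizer_genes={"GENE0002", "GENE0007"},
        sensitizer_survival_multiplier=0.1,
        seed=7,
    )
    control, treated, truth = ss.simulate_screen(params, small_library)
    return control, treated, truth


def brute_force_hits(ratios: pd.DataFrame, ratio_threshold: float, min_concordant: int):
    """Independent double-loop hit caller used as an oracle."""
    out = {}
    usable = ratios[ratios["usable"]] if "usable" in ratios else ratios
    for gene in sorted(set(usable["gene"])):
        rs = usable.loc[usable["gene"] == gene, "ratio"].tolist()
        n_depleted = 0
        for r in rs:
            if r < ratio_threshold:
                n_depleted += 1
        out[gene] = (n_depleted, n_depleted >= min_concordant)
    return out


def brute_force_assign(barcode: str, entries: pd.DataFrame, max_mismatch: int):
    """Exhaustive Hamming scan oracle for barcode assignment."""
    best, best_d = [], None
    for _, row in entries.iterrows():
        if len(row["barcode"]) != len(barcode):
            continue
        d = sum(a != b for a, b in zip(barcode, row["barcode"]))
        if best_d is None or d < best_d:
            best, best_d = [row["shrna_id"]], d
        elif d == best_d:
            best.append(row["shrna_id"])
    if best_d is None or best_d > max_mismatch or len(best) > 1:
        return None
    return best[0]
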