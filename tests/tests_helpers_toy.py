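"""Shared toy CountTable writer for CLI tests."""

import pandas as pd

from hsrkinetics import CountTable


def write_toy_table(path, drop_nhs=False, n_genes=5):
    """Uniform 10-fold untreated / 3-fold CHX induction across genes."""
    rows = {
        f"g{i}": {
            "NHS_untreated_1": 10, "NHS_untreated_2": 10,
            "HS_untreated_1": 100, "HS_untreated_2": 100,
            "NHS_CHX_1": 10, "NHS_CHX_2": 10,
            "HS_CHX_1": 30, "HS_CHX_2": 30,
        }
        for i in range(n_genes)
    }
    counts = pd.DataFrame(rows).T
    counts.index.name = "gene"
    meta = []
    for name in counts.columns:
        heat, chx, rep = name.split("_")
        meta.append({"sample": name, "heat": heat, "chx": chx, "replicate": rep})
    samples = pd.DataFrame(meta).set_index("sample")
    if drop_nhs:
        keep = [c for c in counts.columns if not c.startswith("NHS_CHX")]
        counts, samples = counts[keep], samples.loc[keep]
    CountTable(counts=counts, samples=samples).to_csv(path)
    return path
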