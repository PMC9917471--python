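"""Regenerate the deterministic bundled fixtures (plain text).

Run from the repository root:

    python scripts/make_fixtures.py
"""

from pathlib import Path

import pandas as pd

from rgstab.simulate import (
    study_like_count_spec,
    study_like_cq_spec,
    simulate_cq,
    simulate_counts,
)

DATA = Path(__file__).resolve().parents[1] / "src" / "rgstab" / "fixtures" / "data"


def main() -> None:
    table = simulate_cq(study_like_cq_spec(seed=20230203, unstable_gene="VHA-H", effect=2.5))
    table.data.to_csv(DATA / "study_like_cq.csv", index=False, float_format="%.6f")

    cm, truth = simulate_counts(study_like_count_spec(seed=20230203))
    cm.counts.to_csv(DATA / "study_like_counts.tsv", sep="\t", index_label="gene")
    pd.DataFrame(
        {"sample_id": list(cm.groups), "group": list(cm.groups.values())}
    ).to_csv(DATA / "study_like_design.tsv", sep="\t", index=False)
    truth.data.to_csv(DATA / "study_like_de_truth.csv", index=False, float_format="%.6f")
    print("fixtures written to", DATA)


if __name__ == "__main__":
    main()
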