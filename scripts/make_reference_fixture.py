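"""Regenerate the packaged synthetic reference fixture.

Writes the reference alignment (the four synthetic class templates, which
share one coordinate system and need no gaps) and the column→feature map
into src/shspkit/data/.  Run from the repository root after changing the
template layout in shspkit.synth.
"""

from pathlib import Path

from shspkit.synth import (
    ACD,
    BETA7_ARG_COLUMN,
    C_EXT,
    FEATURE_LAYOUT,
    TEMPLATES,
    TEMPLATE_LENGTH,
)

DATA = Path(__file__).resolve().parent.parent / "src" / "shspkit" / "data"


def main() -> None:
    with open(DATA / "synthetic_reference_alignment.fasta", "w") as fh:
        for label, template in sorted(TEMPLATES.items()):
            fh.write(f">{label} synthetic class template\n{template.sequence}\n")

    feature_of = {}
    for feat, (lo, hi) in FEATURE_LAYOUT.items():
        for col in range(lo, hi + 1):
            feature_of[col] = feat
    with open(DATA / "synthetic_feature_map.tsv", "w") as fh:
        fh.write("column\tregion\tfeature\tmarker\n")
        for col in range(1, TEMPLATE_LENGTH + 1):
            if col < ACD[0]:
                region = "n_arm"
            elif col <= ACD[1]:
                region = "acd"
            else:
                region = "c_ext"
            feature = feature_of.get(col, "none")
            marker = "beta7_arg" if col == BETA7_ARG_COLUMN else "none"
            fh.write(f"{col}\t{region}\t{feature}\t{marker}\n")
    print(f"wrote fixtures under {DATA}")


if __name__ == "__main__":
    main()
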