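#!/usr/bin/env python
"""Concordance of in vivo enhancer activity with in silico classification.

Cross-tabulates each region's transgenic-assay outcome against its
independent chromatin-state designation (relative enhancer/promoter marks
in cultured arterial vs venous human ECs).

Finding: the in vitro labels predict in vivo behaviour poorly. Only 3/15
in vivo-validated arterial enhancers are labelled "Arterial enhancer"
(5/15 "Common EC enhancer", 4/15 TSS, 3/15 uncalled), and 7/8 previously
published arterial enhancers are labelled common rather than arterial.
"""

from pathlib import Path

from artenh.class_summary import concordance
from artenh.datasets import load_transgenic_screen, screen_enhancer_records

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    screen = load_transgenic_screen()

    validated = screen_enhancer_records(screen, published=False, in_vivo_class="arterial")
    t_validated = concordance(validated)
    print(f"validated arterial enhancers (novel screen): {len(validated)}")
    print(t_validated.counts.to_string(), "\n")

    published = screen_enhancer_records(screen, published=True)
    t_published = concordance(published)
    print(f"previously published arterial enhancers: {len(published)}")
    print(t_published.counts.to_string(), "\n")

    everything = screen_enhancer_records(screen)
    t_all = concordance(everything)
    print("full screen contingency (all rows):")
    print(t_all.counts.to_string())

    RESULTS.mkdir(exist_ok=True)
    t_validated.counts.to_csv(RESULTS / "concordance_validated_arterial.tsv", sep="\t")
    t_published.counts.to_csv(RESULTS / "concordance_published_arterial.tsv", sep="\t")
    t_all.counts.to_csv(RESULTS / "concordance_all.tsv", sep="\t")
    print(f"\nwritten: {RESULTS}/concordance_*.tsv")


if __name__ == "__main__":
    main()
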