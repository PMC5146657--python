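"""Classify SSR markers from full-sib pedigree segregation.

Builds a tiny pedigree (two diploid parents, six progeny) for three
markers — a clean AB x CD cross, an AB x BC cross with a legitimate BB
homozygote, and a marker with a null-allele signature — and prints each
marker's verdict.
"""

from salixploidy import AlleleSet, PedigreeGenotypes, check_single_copy


def family(marker, mother, father, progeny):
    return PedigreeGenotypes(
        marker,
        AlleleSet(marker, "mother", mother),
        AlleleSet(marker, "father", father),
        tuple(AlleleSet(marker, f"F1_{i}", p) for i, p in enumerate(progeny, 1)),
    )


families = [
    # AB x CD: all progeny show one maternal + one paternal allele
    family("WSSR_A", (168, 172), (176, 180),
           [(168, 176), (168, 180), (172, 176), (172, 180), (168, 176), (172, 180)]),
    # AB x BC: the (172,) progeny is the legal BB homozygote
    family("WSSR_B", (168, 172), (172, 176),
           [(168, 172), (168, 176), (172,), (172, 176), (168, 176), (172,)]),
    # AB x CD with a one-allele progeny: a paternal allele failed to amplify
    family("WSSR_C", (200, 204), (208, 212),
           [(200, 208), (204,), (200, 212), (204, 208), (200, 208), (204, 212)]),
]

for ped in families:
    v = check_single_copy(ped)
    reasons = ", ".join(r.value for r in v.failure_reasons) or "-"
    print(f"{ped.marker_id}: cross={v.cross_type.value:14s} "
          f"single_copy={v.single_copy!s:5s} fully_informative={v.fully_informative!s:5s} "
          f"reasons={reasons}")

print()
print("A marker is usable for ploidy screening only when it is single-copy")
print("(every progeny explainable as one maternal + one paternal gamete) and")
print("fully informative (AB x CD or AB x BC parents).")
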