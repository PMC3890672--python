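"""Build the diagnostic key from the packaged character matrix.

Prints the private/shared sharing partition of the 136 sampled individuals,
the species diagnosable from their composite haplotypes alone, and a
maternal-parent query: a hybrid's chloroplast profile identifies its seed
parent when that profile is private.
"""

from phoenixbarcode import (
    build_key_from_rows,
    identify_candidates,
    load_character_matrix,
    summarize_sharing,
)
from phoenixbarcode.characters import profile_from_row

rows = load_character_matrix()
key = build_key_from_rows(rows)
s = summarize_sharing(key)

print(f"{key.n_individuals} individuals, {len(key.entries)} distinct composite profiles")
print(f"  in single-species profiles: {s.n_single:>3} ({s.pct_single}%)")
print(f"  shared by two species:      {s.n_two:>3} ({s.pct_two}%)")
print(f"  shared by three species:    {s.n_three_plus:>3} ({s.pct_three_plus}%)")
print(f"\ndiagnosable species ({len(s.diagnosable)}/13): {', '.join(sorted(s.diagnosable))}")

# maternal-parent identification: a dactylifera x canariensis hybrid carries
# its seed parent's chloroplast; the haplotype-4 profile is private
hybrid_cp = profile_from_row(next(r for r in rows if r.species == "canariensis"))
species, match_class = identify_candidates(hybrid_cp, key)
print(f"\nhybrid chloroplast query -> {match_class}: {', '.join(sorted(species))}")

# the date-palm-complex haplotype-2 profile is shared by three species
shared = profile_from_row(next(r for r in rows if r.row_id == "r17"))
species, match_class = identify_candidates(shared, key)
print(f"haplotype-2 query        -> {match_class}: {', '.join(sorted(species))}")
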