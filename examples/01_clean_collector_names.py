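"""Turn messy recordedBy strings into canonical collector identifiers.

Collection data joins collector names with inconsistent delimiters and
spells the same person several ways.  This walks a few raw strings through
atomization and normalization, then resolves a small record batch with a
variant->canonical name map.
"""

from colnet import atomize, normalize, resolve
from colnet.occurrence_io import OccurrenceRecord

for raw in ["Irwin, H.S.; Ratter, J.A.", "Silva, M. et al.", "C.E.B. Proença | howard s. irwin"]:
    names, et_al = atomize(raw)
    tokens = [normalize(n) for n in names]
    print(f"{raw!r:45} -> {tokens}" + ("  [+ unnamed collaborators]" if et_al else ""))

records = [
    OccurrenceRecord("r0", "Irwin, H.; Irwin, H.S.", "Myrtia alba"),
    OccurrenceRecord("r1", "123; s.n.; Proença, C.E.B.", "Fabia minor"),
]
resolved, report = resolve(records, name_map={"irwin,h": "irwin,hs"})
for rec in resolved:
    print(rec.record_id, "->", rec.collector_ids)
print(f"rejected tokens: {[(t, why) for _, t, why in report.rejected_tokens]}")
# The first record collapses to a single id: both spellings are one person,
# so no spurious self-collaboration can enter the coworking network.
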