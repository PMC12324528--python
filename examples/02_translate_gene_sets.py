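"""Translate symbol-space gene sets into SOMAmer (SeqId) space.

Builds a toy annotation world — including a gene targeted by two SOMAmers
and a gene reachable only through a legacy alias — and translates a
symbol-space collection into SeqIds, dropping sets that end up below the
minimum size.
"""

from somamod import translate_collection
from somamod.synthetic import make_toy_annotation

annotation, aliases, collection = make_toy_annotation(seed=7)
translated, report = translate_collection(collection, annotation, aliases, n_min=10)

print(f"annotation: {len(annotation.pairs)} SeqId-symbol pairs, "
      f"{len(annotation.by_symbol)} symbols")
print(f"translated {report.n_translated}/{report.n_input_sets} sets "
      f"({report.n_dropped_small} dropped below n_min=10)")
for s in translated:
    print(f"  {s.set_id} ({s.description}): {len(s.members)} SeqIds, "
          f"e.g. {', '.join(s.members[:3])} ...")
# Parent ids carry the '.0' suffix; the index is the set's position in the
# source collection, so ids stay stable when thresholds change.
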