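"""De novo discovery of the trans-splice leader from transcript 5' ends.

Plants the 44-nt Macrostomum lignano leader on 30% of 2,000 random
transcripts, recovers it from 19-mer frequencies in the first 100 nt, and
classifies each transcript as trans-spliced.
"""

import neoblastsig as nb

config = nb.SimulationConfig(n_clusters=5, n_transcripts=2000, leader_fraction=0.3, seed=5)
records, truth = nb.generate_transcripts(config)

census = nb.kmer_census(records, k=19, window=100)
call = nb.reconstruct_leader(census)
print(f"consensus ({len(call.consensus)} nt, {call.support} supporting transcripts):")
print(f"  {call.consensus}")
print(f"matches the planted leader exactly: {call.consensus == nb.SL_LEADER}")

flags = nb.classify_transspliced(records, call.consensus)
tp = sum(flags.flags[t] for t in truth if truth[t])
fp = sum(flags.flags[t] for t in truth if not truth[t])
n_true = sum(truth.values())
print(f"\ntrans-spliced calls: {sum(flags.flags.values())} of {len(records)} "
      f"(planted {n_true}; sensitivity {tp / n_true:.3f}, false positives {fp})")
print("\nthe leader's 26 internal 19-mers dominate the census because every"
      "\ntrans-spliced mRNA shares the same 5' sequence; random 19-mers almost"
      "\nnever recur across transcripts.")
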