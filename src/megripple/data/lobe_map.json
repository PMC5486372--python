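{
  "_comment": "Best-effort mapping of the cohort table's free-text ripple-location strings onto the canonical lobe vocabulary (L/R x frontal/temporal/parietal/occipital/central). Compound descriptors are split; 'some widespread' maps to 'unknown'; 'N' means no ripples.",
  "N": [],
  "L frontal + occipital": ["L-frontal", "L-occipital"],
  "Bilateral frontal + some widespread": ["L-frontal", "R-frontal", "unknown"],
  "R central": ["R-central"],
  "R centro-temporal": ["R-central", "R-temporal"],
  "R temporo-occipital": ["R-temporal", "R-occipital"],
  "R frontal + L temporal": ["R-frontal", "L-temporal"],
  "R frontal + R fronto-central": ["R-frontal", "R-central"],
  "R > L parieto-occipital": ["R-parietal", "R-occipital", "L-parietal", "L-occipital"],
  "L fronto-temporal + R occipital": ["L-frontal", "L-temporal", "R-occipital"],
  "R temporal": ["R-temporal"],
  "R temporal posterior": ["R-temporal"],
  "Bilateral frontal": ["L-frontal", "R-frontal"],
  "R parieto-occipital + some widespread": ["R-parietal", "R-occipital", "unknown"],
  "R parietal": ["R-parietal"],
  "R central + L temporal + R occipital": ["R-central", "L-temporal", "R-occipital"]
}
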