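# How JCAMP-DX labelled-data-records map onto the scientific data model.
# Keys are normalized LDR labels (uppercase, spaces/dashes/underscores removed).
# target: root  -> document root metadata under `key`
# target: aspect -> the measurement aspect's metadata under `key`
# target: facet -> the substance facet's metadata under `key`
# LDRs absent from this table land in the measurement aspect verbatim,
# under their lowercased label; structural LDRs (the data table and its
# scaling records) are consumed by the decoder and never copied.
TITLE: {target: root, key: title}
ORIGIN: {target: root, key: publisher}
OWNER: {target: root, key: rights}
DATE: {target: root, key: date}
LONGDATE: {target: root, key: date}
DATATYPE: {target: aspect, key: technique}
SPECTROMETERDATASYSTEM: {target: aspect, key: instrument}
INSTRUMENT: {target: aspect, key: instrument}
INSTRUMENTPARAMETERS: {target: aspect, key: settings}
MOLFORM: {target: facet, key: formula}
CASNAME: {target: facet, key: name}
NAMES: {target: facet, key: name}
CASREGISTRYNO: {target: facet, key: casrn}
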