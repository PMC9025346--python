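assemblies	families
AFTD+AMDS+APMK	6A, 9A, 11A, 13A, 18A, 18B, 19B, 20B, 23A, 24A, 24B, 25A, 25B, 26A, 33A, 46A, 65A, 72A, 77A, 79A, 84A, 84B, 141A, 154A, 272A, 291A, 304A, 669A
AFTD+AMDS	17B, 21C, 21D, 22A, 23B, 26B, 27B, 30B, 31A, 31B, 32A, 32B, 33B, 36A, 51B, 58A, 60A, 63A, 72B, 94A, 100A, 104A, 170A, 180A, 450A, 1464A
AFTD+APMK	20A, 62A, 616A
AMDS+APMK	27A, 87A, 146A
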