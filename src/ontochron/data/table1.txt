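Barbus_barbus_0% 00000000000000000000000000000000000000000000000000000
Tinca_tinca_0% 00000000000000000000000000000000000000000000000000000
Hucho_hucho_0% 00000000000000000000000000000000000000000000000000000
Thymallus_thymallus_0% 00000000000000000000000000000000000000000000000000000
Barbus_barbus_5% 1111111111111110000000?000000000000000000000000000000
Barbus_barbus_10% 1111111111111111111111?000000000000000000000000000000
Barbus_barbus_20% 1111111111111111111111?111111111110000000000000000000
Barbus_barbus_25% 1111111111111111111111?111111111111110000000000000000
Barbus_barbus_50% 1111111111111111111111?111111111111111111111111000000
Barbus_barbus_75% 1111111111111111111111?111111111111111111111111111100
Barbus_barbus_100% 1111111111111111111111?111111111111111111111111111111
Tinca_tinca_5% 11111111111111111101100000000000000000000000000000000
Tinca_tinca_10% 11111111111111111101110101111000000000000000000000000
Tinca_tinca_20% 11111111111111111111111111111111010100000000000000000
Tinca_tinca_25% 11111111111111111111111111111111010100010000000000000
Tinca_tinca_50% 11111111111111111111111111111111111111011010101100000
Tinca_tinca_75% 11111111111111111111111111111111111111111111101100000
Tinca_tinca_100% 11111111111111111111111111111111111111111111111111111
Hucho_hucho_5% 11111111100000000000000000000000001000000000000000000
Hucho_hucho_10% 11111111111100000000000000000000001000000000000000000
Hucho_hucho_20% 11111111111111111101100010000000001000000000000000000
Hucho_hucho_25% 11111111111111111101110010111000001000000000000000000
Hucho_hucho_50% 11111111111111111111111111111111111111110100010010000
Hucho_hucho_75% 11111111111111111111111111111111111111111111111111110
Hucho_hucho_100% 11111111111111111111111111111111111111111111111111111
Thymallus_thymallus_5% 1111111111000000000000000000?000?000?000?000000000000
Thymallus_thymallus_10% 1111111111111111000000000001?000?000?000?000000000000
Thymallus_thymallus_20% 1111111111111111111111001111?011?100?000?000000000000
Thymallus_thymallus_25% 1111111111111111111111111111?011?100?100?000000000000
Thymallus_thymallus_50 1111111111111111111111111111?111?111?111?110000000000
Thymallus_thymallus_75% 1111111111111111111111111111?111?111?111?111111110010
Thymallus_thymallus_100% 1111111111111111111111111111?111?111?111?111111111111
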