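# Published reference values: estimated bean production losses due to ozone
# per Ugandan sub-region, 2015, tonnes, by growing season. Karamoja has a
# single (unimodal) growing season, reported in the season1 column.
sub_region,region,season1,season2
North Buganda,Central,10235,5602
South Buganda,Central,5662,5365
Bukedi,Eastern,899,604
Busoga,Eastern,6134,1409
Elgon,Eastern,3785,1705
Teso,Eastern,13,6
Acholi,Northern,18496,15556
Lango,Northern,20773,7405
West Nile,Northern,5127,9300
Karamoja,Northern,2338,
Ankole,Western,19825,11077
Bunyoro,Western,10722,4385
Kigezi,Western,1853,1835
Tooro,Western,8494,5888
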