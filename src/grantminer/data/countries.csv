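country,who_region,income_group,gdp_per_capita
United States of America,Americas,high,57900
United Kingdom,Europe,high,41100
Canada,Americas,high,42300
Sweden,Europe,high,51600
Germany,Europe,high,42100
Ireland,Europe,high,63200
France,Europe,high,36900
Netherlands,Europe,high,45600
Switzerland,Europe,high,80100
Japan,Western Pacific,high,38800
Australia,Western Pacific,high,49900
Saudi Arabia,Eastern Mediterranean,high,19900
South Africa,Africa,upper_middle,5300
Brazil,Americas,upper_middle,8700
Mexico,Americas,upper_middle,8700
China,Western Pacific,upper_middle,8100
Fiji,Western Pacific,upper_middle,5200
Thailand,South-East Asia,upper_middle,5900
Bulgaria,Europe,upper_middle,7500
Iraq,Eastern Mediterranean,upper_middle,4600
Kenya,Africa,lower_middle,1500
Nigeria,Africa,lower_middle,2200
Ghana,Africa,lower_middle,1900
India,South-East Asia,lower_middle,1700
Indonesia,South-East Asia,lower_middle,3600
Viet Nam,Western Pacific,lower_middle,2200
Egypt,Eastern Mediterranean,lower_middle,3500
Ukraine,Europe,lower_middle,2200
Bolivia,Americas,lower_middle,3100
Ethiopia,Africa,low,700
Uganda,Africa,low,600
Malawi,Africa,low,300
Mozambique,Africa,low,400
Afghanistan,Eastern Mediterranean,low,600
Nepal,South-East Asia,low,800
Haiti,Americas,low,800
Democratic People's Republic of Korea,South-East Asia,low,
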