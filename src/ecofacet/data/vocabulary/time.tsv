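id	label	facet_path	parent_id	definition	uri	status	synonyms	seconds
time-unit-second	Second	time/unit		Time-unit class 'Second' (1 seconds).		core		1
time-unit-minute	Minute	time/unit		Time-unit class 'Minute' (60 seconds).		core		60
time-unit-hour	Hour	time/unit		Time-unit class 'Hour' (3600 seconds).		core		3600
time-unit-day	Day	time/unit		Time-unit class 'Day' (86400 seconds).		core		86400
time-unit-week	Week	time/unit		Time-unit class 'Week' (604800 seconds).		core		604800
time-unit-month	Month	time/unit		Time-unit class 'Month' (2592000 seconds).		core		2592000
time-unit-year	Year	time/unit		Time-unit class 'Year' (31536000 seconds).		core		31536000
time-unit-decade	Decade	time/unit		Time-unit class 'Decade' (315360000 seconds).		core		315360000
time-zone-utc	UTC	time/zone		IANA time zone database identifier 'UTC'.		core		
time-zone-europe-berlin	Europe/Berlin	time/zone		IANA time zone database identifier 'Europe/Berlin'.		core		
time-zone-europe-london	Europe/London	time/zone		IANA time zone database identifier 'Europe/London'.		core		
time-zone-europe-paris	Europe/Paris	time/zone		IANA time zone database identifier 'Europe/Paris'.		core		
time-zone-europe-madrid	Europe/Madrid	time/zone		IANA time zone database identifier 'Europe/Madrid'.		core		
time-zone-europe-moscow	Europe/Moscow	time/zone		IANA time zone database identifier 'Europe/Moscow'.		core		
time-zone-america-new-york	America/New_York	time/zone		IANA time zone database identifier 'America/New_York'.		core		
time-zone-america-chicago	America/Chicago	time/zone		IANA time zone database identifier 'America/Chicago'.		core		
time-zone-america-denver	America/Denver	time/zone		IANA time zone database identifier 'America/Denver'.		core		
time-zone-america-los-angeles	America/Los_Angeles	time/zone		IANA time zone database identifier 'America/Los_Angeles'.		core		
time-zone-america-edmonton	America/Edmonton	time/zone		IANA time zone database identifier 'America/Edmonton'.		core		
time-zone-america-sao-paulo	America/Sao_Paulo	time/zone		IANA time zone database identifier 'America/Sao_Paulo'.		core		
time-zone-africa-nairobi	Africa/Nairobi	time/zone		IANA time zone database identifier 'Africa/Nairobi'.		core		
time-zone-africa-johannesburg	Africa/Johannesburg	time/zone		IANA time zone database identifier 'Africa/Johannesburg'.		core		
time-zone-asia-tokyo	Asia/Tokyo	time/zone		IANA time zone database identifier 'Asia/Tokyo'.		core		
time-zone-asia-shanghai	Asia/Shanghai	time/zone		IANA time zone database identifier 'Asia/Shanghai'.		core		
time-zone-asia-kolkata	Asia/Kolkata	time/zone		IANA time zone database identifier 'Asia/Kolkata'.		core		
time-zone-australia-sydney	Australia/Sydney	time/zone		IANA time zone database identifier 'Australia/Sydney'.		core		
time-zone-pacific-auckland	Pacific/Auckland	time/zone		IANA time zone database identifier 'Pacific/Auckland'.		core		
time-zone-atlantic-reykjavik	Atlantic/Reykjavik	time/zone		IANA time zone database identifier 'Atlantic/Reykjavik'.		core		
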